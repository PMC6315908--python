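"""Synthetic toy systems with exact ground truth.

A *toy protein* is a spherical shell of one-atom pseudo-residues packed on
Fibonacci-sphere lattices at several radii, with optional cylindrical
channels bored through the shell and a spherical solvent-accessible cavity
at the centre.  Point particles ("waters") diffuse by Gaussian steps with
hard-core rejection against the pseudo-atoms, so the accessible region and
the channel mouths are known analytically — every tracking, clustering and
pocket stage can be validated without MD trajectories.

The dynamics are a non-physical surrogate (no forces, no hydrodynamics):
they produce confinement, channel flux and density structure, which is all
the downstream analysis consumes.  A confining ``world_radius`` sphere
keeps escaped particles near the protein so they can re-enter.

`make_toy_msa` plants column-wise conservation structure in a toy MSA:
columns are drawn from a Dirichlet-multinomial over the 20 amino-acid
letters, with a low concentration (near one-hot frequencies) for the
planted conserved columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .evolution import AMINO_ACIDS, Alignment
from .io import FrameSeries, Topology, vdw_radius_for

__all__ = ["ToySystemSpec", "GroundTruth", "ToyProtein", "ToySystem",
           "fibonacci_sphere", "make_toy_protein", "simulate_solvent",
           "make_toy_system", "make_toy_msa"]


@dataclass
class ToySystemSpec:
    """Parameters of the toy shell protein and its solvent run.

    Defaults give a ~6 Å accessible cavity behind a 3 Å-thick shell with
    ~4 Å-bore channels: wide enough for the 1 Å probe to thread with the
    2.5 Å hard-core clearance, narrow enough to keep distinct mouths.
    ``shell_outer_radius=None`` derives the shell so that the hard-core
    rule confines particle centres to exactly ``cavity_radius``:
    inner wall = cavity_radius + atom_radius + probe_radius.
    """

    cavity_radius: float = 6.0
    shell_thickness: float = 3.0
    atom_radius: float = 1.5
    probe_radius: float = 1.0
    shell_outer_radius: float | None = None
    channels: Sequence[tuple[Sequence[float], float]] = field(default_factory=list)
    lattice_spacing: float = 1.8
    n_particles: int = 50
    n_frames: int = 1000
    step_size: float = 0.8
    world_radius: float | None = None
    dt_ps: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shell_outer_radius is None:
            self.shell_outer_radius = (self.cavity_radius + self.atom_radius
                                       + self.probe_radius + self.shell_thickness)
        if self.world_radius is None:
            self.world_radius = self.shell_outer_radius + 8.0
        if self.cavity_radius >= self.inner_radius:
            raise ValueError("cavity radius must be < shell inner radius")
        for axis, bore in self.channels:
            if bore <= self.step_size / 2:
                raise ValueError("channel bore must exceed half the step size")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @property
    def inner_radius(self) -> float:
        return self.shell_outer_radius - self.shell_thickness

    @property
    def clearance(self) -> float:
        """Hard-core rejection distance between probe and pseudo-atom centres."""
        return self.atom_radius + self.probe_radius

    def channel_axes(self) -> list[np.ndarray]:
        axes = []
        for axis, _ in self.channels:
            a = np.asarray(axis, dtype=float)
            axes.append(a / np.linalg.norm(a))
        return axes


@dataclass
class GroundTruth:
    """Analytic facts about a toy system.

    ``mouth_centers`` sit where each channel opens into the accessible
    cavity (axis × inner wall radius): after surface trimming, inlets
    accumulate at the inner end of the mouth funnel, so this is the
    reference location cluster centroids are validated against.
    """

    mouth_centers: np.ndarray          # (n_channels, 3) at the inner wall
    cavity_volume: float               # 4/3 π r³, Å³
    object_center: np.ndarray          # (3,)
    cavity_radius: float


@dataclass
class ToyProtein:
    topology: Topology
    coords: np.ndarray                 # (n_atoms, 3) frame-0 positions
    ground_truth: GroundTruth


@dataclass
class ToySystem:
    """Combined protein + solvent toy system ready for the pipeline."""

    topology: Topology                 # protein + solvent atoms
    frames: FrameSeries
    ground_truth: GroundTruth
    spec: ToySystemSpec
    n_protein_atoms: int


def fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """`n` near-uniform deterministic points on a sphere of given radius."""
    i = np.arange(n, dtype=float)
    golden = (1 + 5 ** 0.5) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / golden
    r_xy = np.sqrt(np.maximum(0.0, 1 - z * z))
    pts = np.stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z], axis=1)
    return pts * radius


def make_toy_protein(spec: ToySystemSpec) -> ToyProtein:
    """Build the shell lattice, carve the channels, assemble the topology.

    Every pseudo-atom is a one-atom residue named CA (so the default
    Cα scope selection applies).  Deterministic: no randomness is used.
    """
    layers = []
    r = spec.inner_radius
    while r <= spec.shell_outer_radius + 1e-9:
        n = max(int(np.ceil(4 * np.pi * r * r / spec.lattice_spacing ** 2)), 32)
        layers.append(fibonacci_sphere(n, r))
        r += spec.lattice_spacing * 0.8
    pts = np.concatenate(layers)

    keep = np.ones(len(pts), dtype=bool)
    for axis_unit, (_, bore) in zip(spec.channel_axes(), spec.channels):
        t = pts @ axis_unit
        lateral = np.linalg.norm(pts - np.outer(t, axis_unit), axis=1)
        keep &= ~((t > 0) & (lateral < bore))
    if keep.sum() < 0.5 * len(pts):
        raise ValueError("channels remove more than half of the shell")
    pts = pts[keep]

    n = len(pts)
    topo = Topology(
        atom_ids=np.arange(1, n + 1),
        atom_names=np.array(["CA"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        resids=np.arange(1, n + 1),
        resnames=np.array(["PSD"] * n, dtype=object),
        vdw_radii=np.full(n, spec.atom_radius),
    )
    axes = spec.channel_axes()
    mouths = (np.array([a * spec.inner_radius for a in axes])
              if axes else np.empty((0, 3)))
    gt = GroundTruth(mouth_centers=mouths,
                     cavity_volume=4 / 3 * np.pi * spec.cavity_radius ** 3,
                     object_center=np.zeros(3),
                     cavity_radius=spec.cavity_radius)
    return ToyProtein(topo, pts.astype(np.float32), gt)


def simulate_solvent(protein: ToyProtein, spec: ToySystemSpec) -> ToySystem:
    """Diffuse point particles through the toy protein.

    Particles start uniformly inside the cavity; each frame proposes a
    Gaussian displacement (sd = ``step_size`` per axis) that is rejected —
    the particle stays put — if the new position comes within
    ``atom_radius + probe_radius`` of any pseudo-atom centre or beyond the
    ``world_radius`` confinement sphere.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    atoms = protein.coords.astype(float)
    tree = cKDTree(atoms)
    clearance = spec.clearance
    n = spec.n_particles

    pos = _uniform_ball(rng, n, spec.cavity_radius)
    bad = tree.query(pos)[0] < clearance
    while bad.any():
        pos[bad] = _uniform_ball(rng, int(bad.sum()), spec.cavity_radius)
        bad = tree.query(pos)[0] < clearance

    n_prot = len(atoms)
    coords = np.empty((spec.n_frames, n_prot + n, 3), dtype=np.float32)
    coords[:, :n_prot, :] = protein.coords
    coords[0, n_prot:, :] = pos
    for f in range(1, spec.n_frames):
        prop = pos + rng.normal(scale=spec.step_size, size=(n, 3))
        ok = (tree.query(prop)[0] >= clearance) & \
             (np.linalg.norm(prop, axis=1) <= spec.world_radius)
        pos = np.where(ok[:, None], prop, pos)
        coords[f, n_prot:, :] = pos

    pt = protein.topology
    topo = Topology(
        atom_ids=np.concatenate([pt.atom_ids, np.arange(n_prot + 1, n_prot + n + 1)]),
        atom_names=np.concatenate([pt.atom_names, np.array(["O"] * n, dtype=object)]),
        elements=np.concatenate([pt.elements, np.array(["O"] * n, dtype=object)]),
        resids=np.concatenate([pt.resids, np.arange(n_prot + 1, n_prot + n + 1)]),
        resnames=np.concatenate([pt.resnames, np.array(["WAT"] * n, dtype=object)]),
        vdw_radii=np.concatenate([pt.vdw_radii, np.full(n, vdw_radius_for("O"))]),
    )
    frames = FrameSeries(coords, dt_ps=spec.dt_ps)
    return ToySystem(topo, frames, protein.ground_truth, spec, n_prot)


def make_toy_system(spec: ToySystemSpec) -> ToySystem:
    """Convenience: build the toy protein and run the solvent simulation."""
    return simulate_solvent(make_toy_protein(spec), spec)


def _uniform_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1 / 3)
    return v * r[:, None]


def make_toy_msa(n_sequences: int, n_columns: int,
                 conserved_columns: int | Sequence[int],
                 concentrations: tuple[float, float] = (0.05, 5.0),
                 seed: int = 0) -> tuple[Alignment, list[int]]:
    """Toy MSA with planted column-wise conservation structure.

    Each column's letter frequencies are drawn from a symmetric Dirichlet
    over the 20 amino acids: planted conserved columns use the low
    concentration (first element of ``concentrations`` — near one-hot),
    the rest use the high one (near uniform).  ``conserved_columns`` is
    either a count (positions chosen by the seeded RNG) or explicit
    0-based column indices.  Returns the alignment and the conserved
    column indices.
    """
    rng = np.random.default_rng(seed)
    if isinstance(conserved_columns, (int, np.integer)):
        planted = sorted(rng.choice(n_columns, size=int(conserved_columns),
                                    replace=False).tolist())
    else:
        planted = sorted(int(c) for c in conserved_columns)
    planted_set = set(planted)
    low, high = concentrations
    letters = np.array(list(AMINO_ACIDS))
    cols = np.empty((n_columns, n_sequences), dtype="<U1")
    for j in range(n_columns):
        conc = low if j in planted_set else high
        p = rng.dirichlet(np.full(20, conc))
        cols[j] = rng.choice(letters, size=n_sequences, p=p)
    rows = ["".join(cols[:, i]) for i in range(n_sequences)]
    ids = [f"seq{i + 1:04d}" for i in range(n_sequences)]
    return Alignment(ids, rows), planted
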