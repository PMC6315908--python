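"""Solvent density grids, pockets, cavities, hot-spots and wall residues.

All traced-path samples are binned into a regular voxel grid.  The *outer
pocket* is every visited voxel — the maximal space explored by traced
molecules; the *inner pocket* keeps voxels whose occupancy reaches a
threshold and represents the easily accessible volume.  Connected
components of a pocket (26-connectivity) are *cavities*, reported with
water-accessible volumes (#voxels · spacing³) and the residues lining
their walls.  *Hot-spots* are strict local maxima of the density above a
percentile threshold — positions where waters are attracted by favourable
interactions or trapped in hydrophobic cages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import FrameSeries, Topology
from .tracking import OBJECT, RawPath

__all__ = ["DensityGrid", "Cavity", "Pocket", "HotSpot",
           "accumulate_density", "derive_pockets", "detect_hotspots",
           "wall_residues", "trapped_molecules", "write_dx"]


@dataclass
class DensityGrid:
    """Voxelised occupancy counts of traced-molecule positions."""

    origin: np.ndarray            # (3,) Å, corner of voxel (0,0,0)
    spacing: float                # Å
    counts: np.ndarray            # (nx, ny, nz) int64

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if np.any(self.counts < 0):
            raise ValueError("voxel counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def voxel_indices(self, points: np.ndarray) -> np.ndarray:
        """Integer voxel index of each point (may fall outside the grid)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.floor((pts - self.origin) / self.spacing).astype(np.int64)

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin + (idx + 0.5) * self.spacing

    def voxel_volume(self) -> float:
        return float(self.spacing ** 3)


@dataclass
class Cavity:
    """One connected component of a pocket."""

    component_id: int
    voxels: np.ndarray                     # (k, 3) integer indices
    volume: float                          # Å³
    wall_residues: list[int] = field(default_factory=list)


@dataclass
class Pocket:
    """outer or inner pocket: a voxel set with its connected cavities."""

    kind: str                              # "outer" | "inner"
    mask: np.ndarray                       # boolean over the grid
    grid: DensityGrid
    cavities: list[Cavity] = field(default_factory=list)

    @property
    def volume(self) -> float:
        return float(self.mask.sum()) * self.grid.voxel_volume()


@dataclass(frozen=True)
class HotSpot:
    """A strict local maximum of solvent density."""

    position: tuple[float, float, float]   # voxel center, Å
    density: int
    voxel: tuple[int, int, int]
    wall_residues: tuple[int, ...] = ()


def accumulate_density(paths: Sequence[RawPath], spacing: float = 1.0,
                       segments: Sequence[int] | None = None) -> DensityGrid:
    """Bin path samples into a voxel grid.

    By default every sample of every segment type is binned; pass
    ``segments`` (codes from :mod:`soltrack.tracking`) to restrict, e.g.
    to the internal parts only.  Grid bounds are the sample bounding box
    padded by one voxel on each side.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    chunks = []
    for p in paths:
        pts = p.coords
        if segments is not None:
            pts = pts[np.isin(p.labels, list(segments))]
        if len(pts):
            chunks.append(pts)
    if not chunks:
        raise ValueError("no samples to bin: empty grid")
    pts = np.concatenate(chunks)
    lo = pts.min(axis=0) - spacing
    hi = pts.max(axis=0)
    shape = np.floor((hi - lo) / spacing).astype(int) + 2
    idx = np.floor((pts - lo) / spacing).astype(np.int64)
    counts = np.zeros(tuple(shape), dtype=np.int64)
    np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1)
    return DensityGrid(lo, float(spacing), counts)


_CONNECTIVITY = np.ones((3, 3, 3), dtype=bool)   # 26-connected components


def derive_pockets(grid: DensityGrid,
                   inner_threshold: float | None = None
                   ) -> tuple[Pocket, Pocket]:
    """Outer (count ≥ 1) and inner (count ≥ threshold) pockets.

    ``inner_threshold`` defaults to the mean of the nonzero voxel counts.
    Cavity components use 26-connectivity; component volumes sum to the
    pocket volume.
    """
    if grid.total == 0:
        raise ValueError("empty density grid")
    if inner_threshold is None:
        nz = grid.counts[grid.counts > 0]
        inner_threshold = float(nz.mean())
    outer = _make_pocket("outer", grid.counts >= 1, grid)
    inner = _make_pocket("inner", grid.counts >= inner_threshold, grid)
    return outer, inner


def _make_pocket(kind: str, mask: np.ndarray, grid: DensityGrid) -> Pocket:
    labelled, n = ndimage.label(mask, structure=_CONNECTIVITY)
    cavities = []
    order = []
    for comp in range(1, n + 1):
        vox = np.argwhere(labelled == comp)
        order.append((len(vox), comp, vox))
    # report components by descending volume
    order.sort(key=lambda t: (-t[0], t[1]))
    for rank, (k, _, vox) in enumerate(order, start=1):
        cavities.append(Cavity(rank, vox, k * grid.voxel_volume()))
    return Pocket(kind, mask, grid, cavities)


def detect_hotspots(grid: DensityGrid, percentile: float = 95.0,
                    topology: Topology | None = None,
                    frame_coords: np.ndarray | None = None,
                    wall_cutoff: float = 4.5) -> list[HotSpot]:
    """Strict local density maxima above a percentile of nonzero counts.

    A voxel qualifies when its count reaches the given percentile of the
    nonzero counts, is ≥ all of its 26 neighbours, and exceeds at least
    one of them (a perfectly flat field has no hot-spot).  Out-of-grid
    neighbours are treated by edge replication.  When a topology and frame
    coordinates are supplied, residues with an atom within ``wall_cutoff``
    of the hot-spot voxel center are attached.
    """
    counts = grid.counts
    nz = counts[counts > 0]
    if nz.size == 0:
        return []
    threshold = np.percentile(nz, percentile)
    footprint = _CONNECTIVITY.copy()
    footprint[1, 1, 1] = False
    nmax = ndimage.maximum_filter(counts, footprint=footprint, mode="nearest")
    nmin = ndimage.minimum_filter(counts, footprint=footprint, mode="nearest")
    mask = (counts >= threshold) & (counts >= nmax) & (counts > nmin)
    spots: list[HotSpot] = []
    for vox in np.argwhere(mask):
        center = grid.voxel_centers(vox)[0]
        walls: tuple[int, ...] = ()
        if topology is not None and frame_coords is not None:
            walls = tuple(wall_residues(vox[None, :], grid, topology,
                                        [frame_coords], wall_cutoff))
        spots.append(HotSpot(tuple(map(float, center)),
                             int(counts[tuple(vox)]), tuple(map(int, vox)),
                             walls))
    spots.sort(key=lambda s: (-s.density, s.voxel))
    return spots


def wall_residues(voxels: np.ndarray, grid: DensityGrid, topology: Topology,
                  frame_coords_list: Sequence[np.ndarray],
                  cutoff: float = 4.5) -> list[int]:
    """Residues with ≥ 1 atom within ``cutoff`` of ≥ 1 member voxel center.

    Computed for each representative frame and unioned; the result is
    sorted by residue id.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    centers = grid.voxel_centers(np.asarray(voxels))
    tree = cKDTree(centers)
    prot = np.flatnonzero(topology.protein_mask)
    found: set[int] = set()
    for coords in frame_coords_list:
        atom_xyz = np.asarray(coords, dtype=float)[prot]
        near = tree.query_ball_point(atom_xyz, r=cutoff)
        hit = np.fromiter((len(n) > 0 for n in near), dtype=bool,
                          count=len(near))
        found.update(int(r) for r in topology.resids[prot[hit]])
    return sorted(found)


def trapped_molecules(paths: Sequence[RawPath], min_dwell_ps: float,
                      region_voxels: np.ndarray, grid: DensityGrid,
                      dt_ps: float = 1.0) -> pd.DataFrame:
    """Report paths dwelling in a voxel region before/after the object.

    For each path the maximal run of consecutive samples whose voxel lies
    in ``region_voxels`` is measured separately before the first object
    entry and after the last object exit; runs lasting at least
    ``min_dwell_ps`` are reported.  Dwell time = run length × ``dt_ps``.
    """
    cols = ["path", "molecule", "where", "dwell_ps", "start_frame"]
    region_voxels = np.asarray(region_voxels)
    if region_voxels.size == 0:
        return pd.DataFrame(columns=cols)
    region = {tuple(v) for v in region_voxels}
    rows = []
    for p in paths:
        obj_idx = np.flatnonzero(p.labels == OBJECT)
        first, last = int(obj_idx[0]), int(obj_idx[-1])
        vox = grid.voxel_indices(p.coords)
        in_region = np.fromiter((tuple(v) in region for v in vox), dtype=bool,
                                count=len(vox))
        for where, sl in (("before_object", slice(0, first)),
                          ("after_object", slice(last + 1, p.n_samples))):
            run, start = _longest_run(in_region[sl])
            dwell = run * dt_ps
            if run and dwell >= min_dwell_ps:
                rows.append({"path": p.path_id, "molecule": p.molecule_id,
                             "where": where, "dwell_ps": dwell,
                             "start_frame": int(p.frames[sl.start + start])})
    return pd.DataFrame(rows, columns=cols)


def _longest_run(mask: np.ndarray) -> tuple[int, int]:
    best = cur = 0
    best_start = cur_start = 0
    for i, v in enumerate(mask):
        if v:
            if cur == 0:
                cur_start = i
            cur += 1
            if cur > best:
                best, best_start = cur, cur_start
        else:
            cur = 0
    return best, best_start


def write_dx(grid: DensityGrid, path: str | Path) -> None:
    """Write the density grid in OpenDX volumetric format."""
    nx, ny, nz = grid.shape
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        "origin {:.6f} {:.6f} {:.6f}".format(*(grid.origin + grid.spacing / 2)),
        f"delta {grid.spacing:.6f} 0.000000 0.000000",
        f"delta 0.000000 {grid.spacing:.6f} 0.000000",
        f"delta 0.000000 0.000000 {grid.spacing:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.counts.astype(float).ravel(order="C")
    for i in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.6g}" for v in flat[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    Path(path).write_text("\n".join(lines) + "\n")


def pseudo_atom_pdb(positions: np.ndarray, path: str | Path,
                    values: Sequence[float] | None = None,
                    resname: str = "SPT") -> None:
    """Dump points as PDB pseudo-atoms (for visual inspection)."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    with open(path, "w") as fh:
        for i, p in enumerate(positions, start=1):
            b = 0.0 if values is None else float(values[i - 1])
            fh.write(
                "HETATM{:5d}  X   {:<4s} {:4d}    {:8.3f}{:8.3f}{:8.3f}"
                "  1.00{:6.2f}\n".format(i % 100000, resname, i % 10000,
                                         p[0], p[1], p[2], min(b, 999.99)))
        fh.write("END\n")
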