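"""Single-config pipeline driver: track → cluster → pockets → evolution.

`RunConfig` holds every parameter of a run (with defaults recorded in the
log); `run_pipeline` executes the requested stages and writes all output
artifacts — paths and inlets CSVs, the flux matrix and a JSON summary, the
OpenDX density grid, cavity/hot-spot reports and the conservation tables.
Identical config + inputs produce byte-identical text outputs: nothing
time- or host-dependent is written.
"""

from __future__ import annotations

import configparser
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import clustering, evolution, pockets, regions, tracking
from .io import (FrameSeries, Selection, Topology, load_system,
                 resolve_selection, write_csv_trajectory, write_multimodel_pdb)
from .synthetic import ToySystemSpec, make_toy_system

__all__ = ["RunConfig", "PipelineError", "PipelineResult", "run_pipeline"]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "HID": "H", "HIE": "H", "HIP": "H",
}


class PipelineError(RuntimeError):
    """Raised with the failing stage's name in the message."""


_KNOWN_KEYS = {
    "input": {"topology", "trajectory"},
    "toy": {"cavity_radius", "shell_thickness", "atom_radius", "probe_radius",
            "shell_outer_radius", "channels", "lattice_spacing", "n_particles",
            "n_frames", "step_size", "world_radius", "dt_ps"},
    "object": {"residues", "radius", "atoms"},
    "scope": {"selection"},
    "barber": {"selection", "min_radius", "vdw_correction"},
    "paths": {"solvent", "gap_tolerance", "write_samples"},
    "clustering": {"eps", "min_samples"},
    "pockets": {"spacing", "inner_threshold", "hotspot_percentile",
                "wall_cutoff", "n_wall_frames", "n_cavities"},
    "evolution": {"msa", "reference_id", "mapping", "alpha", "normalization"},
    "output": {"directory"},
    "run": {"seed"},
}


@dataclass
class RunConfig:
    """All parameters of a pipeline run (text-config representable)."""

    # input: either files or a toy-system spec
    topology: str | None = None
    trajectory: str | None = None
    toy: ToySystemSpec | None = None
    # object / scope / barber
    object_residues: list[int] = field(default_factory=list)
    object_radius: float = 4.0
    object_atoms: str = "all"
    scope_selection: str = "name CA"
    barber_selection: str = "protein"
    barber_min_radius: float = 0.5
    barber_vdw_correction: bool = True
    # tracking
    solvent_selection: str = "solvent"
    gap_tolerance: int = 0
    write_samples: bool = True
    # clustering
    cluster_eps: float = 2.5
    cluster_min_samples: int = 3
    # pockets
    grid_spacing: float = 1.0
    inner_threshold: float | None = None
    hotspot_percentile: float = 95.0
    wall_cutoff: float = 4.5
    n_wall_frames: int = 10
    n_cavities: int = 3
    # evolution
    msa_path: str | None = None
    reference_id: str | None = None
    mapping: str = "auto"              # "auto" | "identity"
    ks_alpha: float = 0.005
    entropy_normalization: str = "alphabet"
    # bookkeeping
    output_dir: str = "soltrack_out"
    seed: int = 0

    @classmethod
    def from_ini(cls, path: str | Path) -> "RunConfig":
        parser = configparser.ConfigParser(inline_comment_prefixes=("#", ";"))
        read = parser.read(str(path))
        if not read:
            raise PipelineError(f"[config] cannot read config file {path}")
        for section in parser.sections():
            if section not in _KNOWN_KEYS:
                raise PipelineError(f"[config] unknown section [{section}]")
            unknown = set(parser[section]) - _KNOWN_KEYS[section]
            if unknown:
                raise PipelineError(
                    f"[config] unknown keys in [{section}]: {sorted(unknown)}")
        cfg = cls()
        g = parser.get

        def has(sec: str, key: str) -> bool:
            return parser.has_option(sec, key) and g(sec, key).strip() != ""

        if has("input", "topology"):
            cfg.topology = g("input", "topology")
        if has("input", "trajectory"):
            cfg.trajectory = g("input", "trajectory")
        if parser.has_section("toy"):
            cfg.toy = _toy_spec_from_section(parser["toy"],
                                             seed=parser.getint("run", "seed",
                                                                fallback=0))
        if has("object", "residues"):
            cfg.object_residues = [int(x) for x in g("object", "residues").split()]
        if has("object", "radius"):
            cfg.object_radius = parser.getfloat("object", "radius")
        if has("object", "atoms"):
            cfg.object_atoms = g("object", "atoms")
        if has("scope", "selection"):
            cfg.scope_selection = g("scope", "selection")
        if has("barber", "selection"):
            cfg.barber_selection = g("barber", "selection")
        if has("barber", "min_radius"):
            cfg.barber_min_radius = parser.getfloat("barber", "min_radius")
        if has("barber", "vdw_correction"):
            cfg.barber_vdw_correction = parser.getboolean("barber", "vdw_correction")
        if has("paths", "solvent"):
            cfg.solvent_selection = g("paths", "solvent")
        if has("paths", "gap_tolerance"):
            cfg.gap_tolerance = parser.getint("paths", "gap_tolerance")
        if has("paths", "write_samples"):
            cfg.write_samples = parser.getboolean("paths", "write_samples")
        if has("clustering", "eps"):
            cfg.cluster_eps = parser.getfloat("clustering", "eps")
        if has("clustering", "min_samples"):
            cfg.cluster_min_samples = parser.getint("clustering", "min_samples")
        if has("pockets", "spacing"):
            cfg.grid_spacing = parser.getfloat("pockets", "spacing")
        if has("pockets", "inner_threshold"):
            cfg.inner_threshold = parser.getfloat("pockets", "inner_threshold")
        if has("pockets", "hotspot_percentile"):
            cfg.hotspot_percentile = parser.getfloat("pockets", "hotspot_percentile")
        if has("pockets", "wall_cutoff"):
            cfg.wall_cutoff = parser.getfloat("pockets", "wall_cutoff")
        if has("pockets", "n_wall_frames"):
            cfg.n_wall_frames = parser.getint("pockets", "n_wall_frames")
        if has("pockets", "n_cavities"):
            cfg.n_cavities = parser.getint("pockets", "n_cavities")
        if has("evolution", "msa"):
            cfg.msa_path = g("evolution", "msa")
        if has("evolution", "reference_id"):
            cfg.reference_id = g("evolution", "reference_id")
        if has("evolution", "mapping"):
            cfg.mapping = g("evolution", "mapping")
        if has("evolution", "alpha"):
            cfg.ks_alpha = parser.getfloat("evolution", "alpha")
        if has("evolution", "normalization"):
            cfg.entropy_normalization = g("evolution", "normalization")
        if has("output", "directory"):
            cfg.output_dir = g("output", "directory")
        if has("run", "seed"):
            cfg.seed = parser.getint("run", "seed")
        return cfg

    def validate(self) -> None:
        if self.toy is None and self.topology is None:
            raise PipelineError("[config] either [input] topology or a [toy] "
                                "section is required")
        for label, p in (("topology", self.topology),
                         ("trajectory", self.trajectory),
                         ("msa", self.msa_path)):
            if p is not None and not Path(p).exists():
                raise PipelineError(f"[config] {label} file not found: {p}")
        if self.toy is None and not self.object_residues:
            raise PipelineError("[config] object residues are required for "
                                "file-based input")


def _toy_spec_from_section(section, seed: int) -> ToySystemSpec:
    kwargs: dict = {"seed": seed}
    floats = {"cavity_radius", "shell_thickness", "atom_radius", "probe_radius",
              "shell_outer_radius", "lattice_spacing", "step_size",
              "world_radius", "dt_ps"}
    ints = {"n_particles", "n_frames"}
    for key, value in section.items():
        value = value.strip()
        if not value:
            continue
        if key == "channels":
            channels = []
            for part in value.split(";"):
                part = part.strip()
                if not part:
                    continue
                axis_str, bore_str = part.split(":")
                axis = [float(x) for x in axis_str.split(",")]
                channels.append((axis, float(bore_str)))
            kwargs["channels"] = channels
        elif key in floats:
            kwargs[key] = float(value)
        elif key in ints:
            kwargs[key] = int(value)
    return ToySystemSpec(**kwargs)


@dataclass
class PipelineResult:
    topology: Topology = None
    frames: FrameSeries = None
    paths: list = field(default_factory=list)
    inlets: list = field(default_factory=list)
    clusters: clustering.InletClusterSet | None = None
    flux: clustering.FluxTable | None = None
    grid: pockets.DensityGrid | None = None
    outer_pocket: pockets.Pocket | None = None
    inner_pocket: pockets.Pocket | None = None
    hotspots: list = field(default_factory=list)
    conservation: dict | None = None
    output_dir: Path | None = None


_ALL_STAGES = ("track", "cluster", "pockets", "evolution")


def run_pipeline(config: RunConfig,
                 stages: Sequence[str] = _ALL_STAGES) -> PipelineResult:
    """Run the requested stages and write their artifacts.

    Stage order is fixed (track → cluster → pockets → evolution); later
    stages pull in the earlier ones they depend on.
    """
    config.validate()
    stages = set(stages)
    if {"cluster", "pockets", "evolution"} & stages:
        stages.add("track")
    if "evolution" in stages and config.msa_path is not None:
        stages.add("pockets")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(output_dir=out)
    log: list[str] = ["soltrack pipeline run", "parameters:"]
    for key, value in sorted(asdict(config).items()):
        log.append(f"  {key} = {value}")

    # ---- load / synthesize -------------------------------------------------
    try:
        if config.toy is not None:
            system = make_toy_system(config.toy)
            topology, frames = system.topology, system.frames
            log.append(f"stage load: toy system, {topology.n_atoms} atoms, "
                       f"{frames.n_frames} frames")
        else:
            topology, frames = load_system(config.topology, config.trajectory)
            log.append(f"stage load: {config.topology}, {topology.n_atoms} "
                       f"atoms, {frames.n_frames} frames")
    except (OSError, ValueError) as err:
        raise PipelineError(f"[load] {err}") from err
    result.topology, result.frames = topology, frames

    # ---- track -------------------------------------------------------------
    if "track" in stages:
        try:
            solvent = resolve_selection(topology, config.solvent_selection,
                                        required=True)
            scope_sel = resolve_selection(topology, config.scope_selection,
                                          required=True)
            scope = _region_provider_scope(topology, frames, scope_sel)
            obj = _region_provider_object(topology, frames, config)
            paths = tracking.extract_paths(frames, solvent, scope, obj,
                                           topology, config.gap_tolerance)
            barber_sel = resolve_selection(topology, config.barber_selection,
                                           required=True)
            paths = tracking.trim_paths(paths, frames, topology, barber_sel,
                                        config.barber_min_radius,
                                        config.barber_vdw_correction)
            paths = [p for p in paths if p.n_samples > 0]
            result.paths = paths
            result.inlets = tracking.detect_inlets(paths)
        except (ValueError, KeyError) as err:
            raise PipelineError(f"[track] {err}") from err
        log.append(f"stage track: {len(result.paths)} paths, "
                   f"{len(result.inlets)} inlets")
        _write_paths_csv(result.paths, out / "paths.csv")
        if config.write_samples:
            _write_samples_csv(result.paths, out / "path_samples.csv")

    # ---- cluster -----------------------------------------------------------
    if "cluster" in stages:
        try:
            result.clusters = clustering.cluster_inlets(
                result.inlets, eps=config.cluster_eps,
                min_samples=config.cluster_min_samples)
            result.flux = clustering.flux_table(result.paths, result.clusters)
        except ValueError as err:
            raise PipelineError(f"[cluster] {err}") from err
        log.append(f"stage cluster: {len(result.clusters.sizes)} clusters, "
                   f"{result.clusters.n_outliers} outliers")
        result.clusters.to_frame().to_csv(out / "inlets.csv", index=False,
                                          float_format="%.4f")
        result.flux.counts.to_csv(out / "flux_counts.csv")
        _write_flux_summary(result, config, out / "flux_summary.json")
        clustering.outlier_paths(result.paths, result.clusters).to_csv(
            out / "outlier_paths.csv", index=False, float_format="%.4f")

    # ---- pockets -----------------------------------------------------------
    if "pockets" in stages:
        try:
            grid = pockets.accumulate_density(result.paths,
                                              spacing=config.grid_spacing)
            outer, inner = pockets.derive_pockets(grid, config.inner_threshold)
            wall_frames = _representative_frames(frames, config.n_wall_frames)
            for pocket in (outer, inner):
                for cav in pocket.cavities[:config.n_cavities]:
                    cav.wall_residues = pockets.wall_residues(
                        cav.voxels, grid, topology, wall_frames,
                        config.wall_cutoff)
            spots = pockets.detect_hotspots(grid, config.hotspot_percentile,
                                            topology, wall_frames[0],
                                            config.wall_cutoff)
        except ValueError as err:
            raise PipelineError(f"[pockets] {err}") from err
        result.grid, result.outer_pocket, result.inner_pocket = grid, outer, inner
        result.hotspots = spots
        log.append(f"stage pockets: outer {outer.volume:.1f} A3 "
                   f"({len(outer.cavities)} components), inner "
                   f"{inner.volume:.1f} A3 ({len(inner.cavities)} components), "
                   f"{len(spots)} hot-spots")
        pockets.write_dx(grid, out / "density.dx")
        _write_cavities_csv(outer, inner, out / "cavities.csv")
        _write_pocket_pdb(inner, out / "pockets.pdb")
        _write_hotspots(spots, out)

    # ---- evolution ---------------------------------------------------------
    if "evolution" in stages and config.msa_path is not None:
        try:
            result.conservation = _run_evolution(config, topology, result, out)
        except (ValueError, KeyError) as err:
            raise PipelineError(f"[evolution] {err}") from err
        n_cav = len(result.conservation["cavities"])
        log.append(f"stage evolution: {n_cav} cavity comparisons at "
                   f"alpha={config.ks_alpha}")

    (out / "run.log").write_text("\n".join(log) + "\n")
    return result


# ---------------------------------------------------------------------------
# helpers


def _region_provider_scope(topology: Topology, frames: FrameSeries,
                           scope_sel: Selection):
    idx = topology.atom_indices(scope_sel.atom_ids)
    pts = frames.coords[:, idx, :]
    if np.all(pts == pts[0]):
        return regions.build_scope(pts[0].astype(float))
    cache: dict = {"t": None, "scope": None}

    def provider(t: int):
        if cache["t"] is not None and np.array_equal(pts[t], pts[cache["t"]]):
            return cache["scope"]
        cache["t"], cache["scope"] = t, regions.build_scope(pts[t].astype(float))
        return cache["scope"]

    return provider


def _region_provider_object(topology: Topology, frames: FrameSeries,
                            config: RunConfig):
    if config.toy is not None and not config.object_residues:
        # toy systems: object sphere at the known cavity centre
        return regions.SphereSet(np.zeros((1, 3)),
                                 np.array([config.object_radius]))
    resids = config.object_residues
    first = regions.build_object(topology, frames.coords[0], resids,
                                 config.object_radius, config.object_atoms)
    mask = np.isin(topology.resids, np.asarray(resids))
    if config.object_atoms == "CA":
        mask &= np.char.upper(topology.atom_names.astype(str)) == "CA"
    pts = frames.coords[:, mask, :]
    if np.all(pts == pts[0]):
        return first

    def provider(t: int):
        return regions.build_object(topology, frames.coords[t], resids,
                                    config.object_radius, config.object_atoms)

    return provider


def _representative_frames(frames: FrameSeries, n: int) -> list[np.ndarray]:
    n = max(1, min(n, frames.n_frames))
    picks = np.linspace(0, frames.n_frames - 1, n).astype(int)
    return [frames.coords[i] for i in np.unique(picks)]


def _write_paths_csv(paths, path: Path) -> None:
    rows = []
    for p in paths:
        sizes = p.segment_sizes()
        rows.append({
            "path": p.path_id, "molecule": p.molecule_id,
            "first_frame": int(p.frames[0]), "last_frame": int(p.frames[-1]),
            "n_samples": p.n_samples, "incoming": sizes["incoming"],
            "object": sizes["object"], "reentry": sizes["reentry"],
            "outgoing": sizes["outgoing"],
            "entry_terminus": p.entry_terminus,
            "exit_terminus": p.exit_terminus,
        })
    cols = ["path", "molecule", "first_frame", "last_frame", "n_samples",
            "incoming", "object", "reentry", "outgoing", "entry_terminus",
            "exit_terminus"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def _write_samples_csv(paths, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("path,frame,x,y,z,label\n")
        for p in paths:
            for f, xyz, lab in zip(p.frames, p.coords, p.labels):
                fh.write(f"{p.path_id},{int(f)},{xyz[0]:.4f},{xyz[1]:.4f},"
                         f"{xyz[2]:.4f},{tracking.LABEL_NAMES[int(lab)]}\n")


def _write_flux_summary(result: PipelineResult, config: RunConfig,
                        path: Path) -> None:
    flux = result.flux
    summary = {
        "seed": config.seed,
        "total_paths": flux.total_paths,
        "empty": bool(flux.empty),
        "clusters": {name: {"size": int(result.clusters.sizes[name]),
                            "centroid": [round(float(v), 4) for v in
                                         result.clusters.centroids[name]]}
                     for name in result.clusters.cluster_names},
        "n_outlier_inlets": result.clusters.n_outliers,
        "inlet_shares_pct": {k: round(float(v), 4)
                             for k, v in flux.inlet_shares().items()},
        "path_shares_pct": {
            f"{e}->{x}": round(float(flux.path_shares().loc[e, x]), 4)
            for e in flux.counts.index for x in flux.counts.columns
            if flux.counts.loc[e, x] > 0},
    }
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def _write_cavities_csv(outer, inner, path: Path) -> None:
    rows = []
    for pocket in (outer, inner):
        for cav in pocket.cavities:
            rows.append({
                "pocket": pocket.kind, "component": cav.component_id,
                "n_voxels": len(cav.voxels),
                "volume_A3": round(cav.volume, 4),
                "wall_residues": " ".join(str(r) for r in cav.wall_residues),
            })
    pd.DataFrame(rows, columns=["pocket", "component", "n_voxels",
                                "volume_A3", "wall_residues"]).to_csv(
        path, index=False)


def _write_pocket_pdb(inner, path: Path) -> None:
    """Inner-pocket voxel centres as pseudo-atoms, B-factor = component id."""
    if not inner.cavities:
        return
    positions = np.concatenate(
        [inner.grid.voxel_centers(c.voxels) for c in inner.cavities])
    values = np.concatenate(
        [np.full(len(c.voxels), c.component_id) for c in inner.cavities])
    pockets.pseudo_atom_pdb(positions, path, values=values, resname="PCK")


def _write_hotspots(spots, out: Path) -> None:
    rows = [{"x": round(s.position[0], 4), "y": round(s.position[1], 4),
             "z": round(s.position[2], 4), "density": s.density,
             "wall_residues": " ".join(str(r) for r in s.wall_residues)}
            for s in spots]
    pd.DataFrame(rows, columns=["x", "y", "z", "density",
                                "wall_residues"]).to_csv(
        out / "hotspots.csv", index=False)
    if spots:
        pockets.pseudo_atom_pdb(np.array([s.position for s in spots]),
                                out / "hotspots.pdb",
                                values=[s.density for s in spots])


def _run_evolution(config: RunConfig, topology: Topology,
                   result: PipelineResult, out: Path) -> dict:
    alignment = evolution.read_alignment(config.msa_path)
    profile = evolution.entropy_profile(alignment,
                                        config.entropy_normalization)
    profile.to_frame().to_csv(out / "entropy.csv", index=False,
                              float_format="%.6f")
    resids = [int(r) for r in np.unique(topology.resids[topology.protein_mask])]
    if config.mapping == "identity":
        ncol = profile.values.size
        resmap = evolution.ResidueMap(
            {r: r for r in resids if 1 <= r <= ncol}, config.reference_id)
    else:
        if config.reference_id is None:
            raise ValueError("evolution mapping=auto requires reference_id")
        seq = _structure_sequence(topology, resids)
        resmap = evolution.map_to_alignment(
            seq, resids, alignment.row_by_id(config.reference_id),
            config.reference_id)
    cavity_lists = {}
    if result.inner_pocket is not None:
        for cav in result.inner_pocket.cavities[:config.n_cavities]:
            if cav.wall_residues:
                cavity_lists[f"cavity_{cav.component_id}"] = cav.wall_residues
    if not cavity_lists:
        raise ValueError("no cavity wall-residue lists available for the "
                         "conservation comparison")
    report = evolution.cavity_conservation_report(profile, resmap,
                                                  cavity_lists,
                                                  alpha=config.ks_alpha)
    report["residue_table"].to_csv(out / "cavity_entropy.csv", index=False,
                                   float_format="%.6f")
    serializable = {
        "alpha": report["alpha"],
        "cavities": {
            name: {"residues": info["residues"],
                   "unmapped": info["unmapped"],
                   "median_entropy": round(info["median_entropy"], 6),
                   "rest_median_entropy": round(info["rest_median_entropy"], 6),
                   "ks_statistic": round(info["ks"].statistic, 6),
                   "ks_pvalue": float(f"{info['ks'].pvalue:.6g}"),
                   "reject": bool(info["ks"].reject)}
            for name, info in report["cavities"].items()},
    }
    (out / "conservation.json").write_text(
        json.dumps(serializable, indent=2, sort_keys=True) + "\n")
    return report


def _structure_sequence(topology: Topology, resids: list[int]) -> str:
    letters = []
    for r in resids:
        resname = str(topology.resnames[topology.resids == r][0]).upper()
        letters.append(_THREE_TO_ONE.get(resname, "X"))
    return "".join(letters)


def write_system(topology: Topology, frames: FrameSeries, out_dir: Path,
                 stem: str = "toy_system") -> tuple[Path, Path]:
    """Write a system in the text fallback dialects (PDB + CSV trajectory)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb = out_dir / f"{stem}.pdb"
    csv = out_dir / f"{stem}_traj.csv"
    write_multimodel_pdb(pdb, topology,
                         FrameSeries(frames.coords[:1]))
    write_csv_trajectory(csv, topology, frames)
    return pdb, csv
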