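"""System input/output: topology, trajectory frames and atom selections.

The analysis pipeline consumes a static :class:`Topology` (atoms, residues,
van der Waals radii, protein/solvent masks) plus a :class:`FrameSeries` of
coordinates.  Standard containers (PDB topology, DCD/XTC trajectories,
multi-model PDB) are read through MDAnalysis; two plain-text fallback
dialects — multi-model PDB and a ``frame,atom_id,x,y,z`` CSV — are written
and read natively so that test fixtures need no binary codecs.

Coordinates are in Å throughout, frames are 0-based and residue ids are
1-based as in PDB.  Periodic images are *not* unwrapped here: input
trajectories are assumed whole-molecule imaged.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Topology",
    "FrameSeries",
    "Selection",
    "load_system",
    "resolve_selection",
    "write_multimodel_pdb",
    "read_multimodel_pdb",
    "write_csv_trajectory",
    "read_csv_trajectory",
]

# Bondi-style van der Waals radii (Å) keyed by element symbol.  The radius
# feeds the Auto-Barber surface correction; unknown elements fall back to
# DEFAULT_VDW_RADIUS with a warning.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "CA": 2.31,
    "ZN": 1.39,
    "FE": 1.94,
    "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.50

#: residue names treated as solvent probes by default
SOLVENT_RESNAMES = {"WAT", "HOH", "SOL", "TIP3", "TIP", "SPC", "T3P"}
#: residue names treated as non-protein ions
ION_RESNAMES = {"NA+", "CL-", "NA", "CL", "K+", "MG2", "CA2", "ZN2", "SOD", "CLA", "POT"}


@dataclass
class Topology:
    """Static description of the system: atoms, residues and masks.

    Atom ids are unique, every atom belongs to exactly one residue, and
    every van der Waals radius is positive (checked in ``__post_init__``).
    """

    atom_ids: np.ndarray          # (n,) int, unique
    atom_names: np.ndarray        # (n,) str
    elements: np.ndarray          # (n,) str, upper-case symbols
    resids: np.ndarray            # (n,) int, 1-based
    resnames: np.ndarray          # (n,) str
    vdw_radii: np.ndarray         # (n,) float, Å
    protein_mask: np.ndarray = field(default=None)  # (n,) bool
    solvent_mask: np.ndarray = field(default=None)  # (n,) bool

    def __post_init__(self) -> None:
        self.atom_ids = np.asarray(self.atom_ids, dtype=np.int64)
        self.resids = np.asarray(self.resids, dtype=np.int64)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.vdw_radii = np.asarray(self.vdw_radii, dtype=float)
        if len(np.unique(self.atom_ids)) != self.n_atoms:
            raise ValueError("atom ids must be unique")
        if np.any(self.vdw_radii <= 0):
            raise ValueError("all van der Waals radii must be > 0")
        if self.solvent_mask is None:
            self.solvent_mask = np.isin(self.resnames.astype(str),
                                        list(SOLVENT_RESNAMES))
        if self.protein_mask is None:
            ion = np.isin(self.resnames.astype(str), list(ION_RESNAMES))
            self.protein_mask = ~self.solvent_mask & ~ion
        self.protein_mask = np.asarray(self.protein_mask, dtype=bool)
        self.solvent_mask = np.asarray(self.solvent_mask, dtype=bool)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    def atom_indices(self, atom_ids: Iterable[int]) -> np.ndarray:
        """Positional indices of the given atom ids (sorted by id)."""
        ids = np.asarray(sorted(atom_ids), dtype=np.int64)
        order = np.argsort(self.atom_ids, kind="stable")
        pos = np.searchsorted(self.atom_ids[order], ids)
        if np.any(pos >= self.n_atoms) or np.any(self.atom_ids[order][pos] != ids):
            missing = ids[(pos >= self.n_atoms) | (self.atom_ids[order][np.minimum(pos, self.n_atoms - 1)] != ids)]
            raise KeyError(f"unknown atom ids: {missing.tolist()}")
        return order[pos]

    def residue_ids(self) -> np.ndarray:
        return np.unique(self.resids)


@dataclass
class FrameSeries:
    """Per-frame coordinates for every atom of a :class:`Topology`.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å.  ``times_ps`` is
    optional; when only a cadence is known use ``dt_ps``.
    """

    coords: np.ndarray
    frame_indices: np.ndarray = None
    dt_ps: float | None = None
    times_ps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float32)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.frame_indices is None:
            self.frame_indices = np.arange(self.n_frames, dtype=np.int64)
        self.frame_indices = np.asarray(self.frame_indices, dtype=np.int64)
        if len(self.frame_indices) != self.n_frames:
            raise ValueError("frame_indices length mismatch")
        if self.n_frames > 1 and np.any(np.diff(self.frame_indices) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if self.times_ps is None and self.dt_ps is not None:
            self.times_ps = self.frame_indices * float(self.dt_ps)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> np.ndarray:
        return self.coords[i]


@dataclass(frozen=True)
class Selection:
    """A selection expression together with its resolved atom ids."""

    expression: str
    atom_ids: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.atom_ids)


class SelectionError(ValueError):
    pass


def _guess_element(atom_name: str, resname: str) -> str:
    name = atom_name.strip()
    if resname.strip().upper() in SOLVENT_RESNAMES and name.upper().startswith("O"):
        return "O"
    # two-letter element if the first two characters form a known symbol
    two = name[:2].upper()
    if two in VDW_RADII and not name[:1].isdigit():
        # avoid mistaking CA (alpha carbon) in amino acids for calcium
        if not (two == "CA" and resname.strip().upper() not in ION_RESNAMES):
            return two
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return name.upper() or "X"


def vdw_radius_for(element: str) -> float:
    r = VDW_RADII.get(element.upper())
    if r is None:
        warnings.warn(
            f"unknown element {element!r}: using default vdW radius "
            f"{DEFAULT_VDW_RADIUS} Å",
            stacklevel=2,
        )
        return DEFAULT_VDW_RADIUS
    return r


# ---------------------------------------------------------------------------
# loading


def load_system(topology_path: str | Path,
                trajectory_path: str | Path | None = None) -> tuple[Topology, FrameSeries]:
    """Read a PDB topology plus an optional trajectory into memory.

    Supported trajectory containers: DCD, XTC, multi-model PDB (all through
    MDAnalysis) and the plain-text CSV dialect ``frame,atom_id,x,y,z``.
    With no trajectory, the topology's own coordinates become a single
    frame.  The trajectory atom count must match the topology.
    """
    topology_path = Path(topology_path)
    topology, topo_coords = _read_pdb_topology(topology_path)
    if trajectory_path is None:
        return topology, FrameSeries(topo_coords[None, :, :])

    trajectory_path = Path(trajectory_path)
    suffix = trajectory_path.suffix.lower()
    if suffix == ".csv":
        frames = read_csv_trajectory(trajectory_path, n_atoms=topology.n_atoms,
                                     atom_ids=topology.atom_ids)
    elif suffix == ".pdb":
        frames = read_multimodel_pdb(trajectory_path)
    else:
        frames = _read_with_mdanalysis(topology_path, trajectory_path)
    if frames.n_atoms != topology.n_atoms:
        raise ValueError(
            f"trajectory has {frames.n_atoms} atoms but topology has "
            f"{topology.n_atoms}")
    return topology, frames


def _read_pdb_topology(path: Path) -> tuple[Topology, np.ndarray]:
    atom_ids, names, elements, resids, resnames, xyz = [], [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("ENDMDL"):
                break
            if not (line.startswith("ATOM") or line.startswith("HETATM")):
                continue
            atom_ids.append(int(line[6:11]))
            name = line[12:16].strip()
            resname = line[17:21].strip()
            names.append(name)
            resnames.append(resname)
            resids.append(int(line[22:26]))
            xyz.append((float(line[30:38]), float(line[38:46]), float(line[46:54])))
            elem = line[76:78].strip().upper() if len(line) >= 78 else ""
            elements.append(elem or _guess_element(name, resname))
    if not atom_ids:
        raise ValueError(f"no ATOM/HETATM records in {path}")
    radii = np.array([vdw_radius_for(e) for e in elements])
    topo = Topology(np.array(atom_ids), np.array(names, dtype=object),
                    np.array(elements, dtype=object), np.array(resids),
                    np.array(resnames, dtype=object), radii)
    return topo, np.asarray(xyz, dtype=np.float32)


def _read_with_mdanalysis(topology_path: Path, trajectory_path: Path) -> FrameSeries:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology_path), str(trajectory_path))
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory],
                          dtype=np.float32)
        try:
            dt = float(u.trajectory.dt)
        except (AttributeError, ValueError):
            dt = None
    return FrameSeries(coords, dt_ps=dt)


# ---------------------------------------------------------------------------
# fallback text formats


def write_multimodel_pdb(path: str | Path, topology: Topology,
                         frames: FrameSeries) -> None:
    """Write frames as MODEL/ENDMDL records (writer precision 1e-3 Å)."""
    with open(path, "w") as fh:
        for f in range(frames.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            xyz = frames.coords[f]
            for i in range(topology.n_atoms):
                name = str(topology.atom_names[i])
                pad_name = f" {name:<3s}" if len(name) < 4 else name[:4]
                fh.write(
                    "ATOM  {:5d} {:<4s}{:<4s} {:4d}    {:8.3f}{:8.3f}{:8.3f}"
                    "  1.00  0.00          {:>2s}\n".format(
                        int(topology.atom_ids[i]) % 100000, pad_name,
                        str(topology.resnames[i])[:4],
                        int(topology.resids[i]) % 10000,
                        xyz[i, 0], xyz[i, 1], xyz[i, 2],
                        str(topology.elements[i])[:2]))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_multimodel_pdb(path: str | Path) -> FrameSeries:
    frames: list[np.ndarray] = []
    current: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("ATOM", "HETATM")):
                current.append((float(line[30:38]), float(line[38:46]),
                                float(line[46:54])))
            elif line.startswith("ENDMDL"):
                frames.append(np.asarray(current, dtype=np.float32))
                current = []
    if current:
        frames.append(np.asarray(current, dtype=np.float32))
    if not frames:
        raise ValueError(f"no coordinate models found in {path}")
    n = {f.shape[0] for f in frames}
    if len(n) != 1:
        raise ValueError("models differ in atom count")
    return FrameSeries(np.stack(frames))


def write_csv_trajectory(path: str | Path, topology: Topology,
                         frames: FrameSeries) -> None:
    """CSV dialect: one row per (frame, atom): frame,atom_id,x,y,z."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "atom_id", "x", "y", "z"])
        for f in range(frames.n_frames):
            xyz = frames.coords[f]
            for i in range(topology.n_atoms):
                writer.writerow([int(frames.frame_indices[f]),
                                 int(topology.atom_ids[i]),
                                 f"{xyz[i, 0]:.4f}", f"{xyz[i, 1]:.4f}",
                                 f"{xyz[i, 2]:.4f}"])


def read_csv_trajectory(path: str | Path, n_atoms: int,
                        atom_ids: Sequence[int] | None = None) -> FrameSeries:
    rows: dict[int, dict[int, tuple[float, float, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip() for h in header[:2]] != ["frame", "atom_id"]:
            raise ValueError("CSV trajectory must start with header frame,atom_id,x,y,z")
        for row in reader:
            f, a = int(row[0]), int(row[1])
            rows.setdefault(f, {})[a] = (float(row[2]), float(row[3]), float(row[4]))
    frame_ids = sorted(rows)
    counts = {len(v) for v in rows.values()}
    if counts != {n_atoms}:
        raise ValueError(
            f"CSV trajectory atom count {sorted(counts)} does not match "
            f"topology ({n_atoms} atoms)")
    if atom_ids is None:
        atom_ids = sorted(rows[frame_ids[0]])
    coords = np.empty((len(frame_ids), n_atoms, 3), dtype=np.float32)
    for fi, f in enumerate(frame_ids):
        per_atom = rows[f]
        try:
            coords[fi] = [per_atom[int(a)] for a in atom_ids]
        except KeyError as err:
            raise ValueError(f"frame {f} is missing atom id {err}") from None
    return FrameSeries(coords, frame_indices=np.asarray(frame_ids))


# ---------------------------------------------------------------------------
# selection mini-language
#
# expr     := term ("or" term)*
# term     := factor ("and" factor)*
# factor   := "(" expr ")" | keyword args
# keywords := resname <names...> | resid <ids/ranges...> | name <names...>
#             | element <symbols...> | protein | solvent | all


def resolve_selection(topology: Topology, expression: str,
                      required: bool = False) -> Selection:
    """Resolve a selection expression to a sorted tuple of atom ids.

    Resolution is deterministic and idempotent for a fixed topology.  With
    ``required=True`` an empty result raises :class:`SelectionError`.
    """
    tokens = expression.replace("(", " ( ").replace(")", " ) ").split()
    if not tokens:
        raise SelectionError("empty selection expression")
    mask, rest = _parse_expr(topology, tokens)
    if rest:
        raise SelectionError(f"trailing tokens in selection: {' '.join(rest)}")
    ids = tuple(int(a) for a in np.sort(topology.atom_ids[mask]))
    if required and not ids:
        raise SelectionError(f"required selection {expression!r} matched no atoms")
    return Selection(expression, ids)


_KEYWORDS = {"resname", "resid", "name", "element", "protein", "solvent",
             "all", "and", "or", "(", ")"}


def _parse_expr(topo: Topology, tokens: list[str]):
    mask, tokens = _parse_term(topo, tokens)
    while tokens and tokens[0] == "or":
        rhs, tokens = _parse_term(topo, tokens[1:])
        mask = mask | rhs
    return mask, tokens


def _parse_term(topo: Topology, tokens: list[str]):
    mask, tokens = _parse_factor(topo, tokens)
    while tokens and tokens[0] == "and":
        rhs, tokens = _parse_factor(topo, tokens[1:])
        mask = mask & rhs
    return mask, tokens


def _parse_factor(topo: Topology, tokens: list[str]):
    if not tokens:
        raise SelectionError("unexpected end of selection expression")
    tok = tokens[0]
    if tok == "(":
        mask, rest = _parse_expr(topo, tokens[1:])
        if not rest or rest[0] != ")":
            raise SelectionError("unbalanced parentheses in selection")
        return mask, rest[1:]
    if tok == "protein":
        return topo.protein_mask.copy(), tokens[1:]
    if tok == "solvent":
        return topo.solvent_mask.copy(), tokens[1:]
    if tok == "all":
        return np.ones(topo.n_atoms, dtype=bool), tokens[1:]
    if tok in ("resname", "name", "element", "resid"):
        args, rest = _collect_args(tokens[1:])
        if not args:
            raise SelectionError(f"{tok} requires at least one argument")
        if tok == "resid":
            ids: set[int] = set()
            for a in args:
                if ":" in a:
                    lo, hi = a.split(":")
                    ids.update(range(int(lo), int(hi) + 1))
                else:
                    ids.add(int(a))
            mask = np.isin(topo.resids, sorted(ids))
        else:
            attr = {"resname": topo.resnames, "name": topo.atom_names,
                    "element": topo.elements}[tok].astype(str)
            mask = np.isin(np.char.upper(attr), [a.upper() for a in args])
        return mask, rest
    raise SelectionError(f"unknown selection token {tok!r}")


def _collect_args(tokens: list[str]):
    args = []
    while tokens and tokens[0] not in _KEYWORDS:
        args.append(tokens[0])
        tokens = tokens[1:]
    return args, tokens
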