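"""Per-molecule path extraction through the scope and object regions.

A *raw path* is the maximal run of consecutive frames a solvent molecule
spends inside the scope, provided it visits the object at least once.  Its
samples are labelled:

* ``incoming`` — before the first object visit,
* ``object``   — inside the object,
* ``reentry``  — outside the object between two object visits,
* ``outgoing`` — after the last object visit.

A terminus that coincides with the first (last) trajectory frame without
crossing the scope boundary carries the ``N`` label (path end detected
inside the protein); crossing termini produce *inlets* — the surface
points where the molecule enters or leaves the macromolecule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .io import FrameSeries, Selection, Topology
from .regions import ConvexScope, SphereSet, barber_trim

__all__ = ["RawPath", "Inlet", "INCOMING", "OBJECT", "OUTGOING", "REENTRY",
           "PENDING", "N_TERMINUS", "extract_paths", "paths_from_membership",
           "segment_path", "detect_inlets", "trim_paths"]

INCOMING, OBJECT, OUTGOING, REENTRY = 0, 1, 2, 3
LABEL_NAMES = {INCOMING: "incoming", OBJECT: "object",
               OUTGOING: "outgoing", REENTRY: "reentry"}

PENDING = "pending"   # terminus crossed the boundary, cluster not yet assigned
N_TERMINUS = "N"      # terminus detected inside the protein


@dataclass
class RawPath:
    """One molecule's traced visit to the object region."""

    path_id: int
    molecule_id: int
    frames: np.ndarray        # (n,) global frame indices, strictly increasing
    coords: np.ndarray        # (n, 3) Å
    labels: np.ndarray        # (n,) segment codes
    entry_terminus: str = PENDING
    exit_terminus: str = PENDING

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if not (len(self.frames) == len(self.coords) == len(self.labels)):
            raise ValueError("frames, coords and labels must align")
        if len(self.frames) > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("path frames must be strictly increasing")
        if self.n_samples and not np.any(self.labels == OBJECT):
            raise ValueError("a raw path must contain at least one object sample")

    @property
    def n_samples(self) -> int:
        return len(self.frames)

    def segment_sizes(self) -> dict[str, int]:
        return {name: int(np.sum(self.labels == code))
                for code, name in LABEL_NAMES.items()}

    def slice(self, start: int, stop: int) -> "RawPath":
        return replace(self, frames=self.frames[start:stop],
                       coords=self.coords[start:stop],
                       labels=self.labels[start:stop])


@dataclass(frozen=True)
class Inlet:
    """Surface crossing point of one path terminus."""

    position: tuple[float, float, float]
    frame: int
    direction: str            # "entry" or "exit"
    path_id: int


def _membership(region, frames: FrameSeries, coords: np.ndarray) -> np.ndarray:
    """(T, M) membership matrix for a static or per-frame region."""
    T, M = coords.shape[:2]
    if isinstance(region, (ConvexScope, SphereSet)):
        return region.contains(coords.reshape(-1, 3)).reshape(T, M)
    out = np.empty((T, M), dtype=bool)
    for t in range(T):
        r = region(t) if callable(region) else region[t]
        out[t] = r.contains(coords[t])
    return out


def extract_paths(frames: FrameSeries, solvent: Selection,
                  scope, obj, topology: Topology,
                  gap_tolerance: int = 0) -> list[RawPath]:
    """Trace every solvent molecule and return its raw paths.

    ``scope`` and ``obj`` may be a single static region, a per-frame
    sequence, or a callable ``frame_index -> region``.  A molecule's probe
    point is a single atom (one per residue of the solvent selection, e.g.
    the water oxygen); its identity is the residue id.  Runs separated by
    more than ``gap_tolerance`` out-of-scope frames become distinct paths.
    """
    if len(solvent) == 0:
        raise ValueError("solvent selection is empty")
    idx = topology.atom_indices(solvent.atom_ids)
    # one probe atom per residue (first by atom id)
    resids = topology.resids[idx]
    _, first = np.unique(resids, return_index=True)
    idx = idx[np.sort(first)]
    mol_ids = topology.resids[idx]

    coords = frames.coords[:, idx, :].astype(float)
    in_scope = _membership(scope, frames, coords)
    in_obj = _membership(obj, frames, coords)
    return paths_from_membership(in_scope, in_obj, coords, mol_ids,
                                 frames.frame_indices, gap_tolerance)


def paths_from_membership(in_scope: np.ndarray, in_object: np.ndarray,
                          coords: np.ndarray, molecule_ids: Sequence[int],
                          frame_indices: np.ndarray | None = None,
                          gap_tolerance: int = 0) -> list[RawPath]:
    """Build raw paths from boolean membership timelines.

    ``in_scope`` and ``in_object`` are (T, M) over frames × molecules;
    ``coords`` is (T, M, 3).  Object membership only counts while in scope.
    This is the bookkeeping core of :func:`extract_paths`, exposed so that
    timeline fixtures can exercise it directly.
    """
    in_scope = np.asarray(in_scope, dtype=bool)
    in_object = np.asarray(in_object, dtype=bool)
    T, M = in_scope.shape
    if frame_indices is None:
        frame_indices = np.arange(T)
    paths: list[RawPath] = []
    pid = 0
    for m in range(M):
        s = in_scope[:, m]
        on = np.flatnonzero(s)
        if on.size == 0:
            continue
        # split runs where the out-of-scope gap exceeds the tolerance
        breaks = np.flatnonzero(np.diff(on) > gap_tolerance + 1)
        starts = np.concatenate(([0], breaks + 1))
        stops = np.concatenate((breaks, [on.size - 1]))
        for a, b in zip(starts, stops):
            lo, hi = int(on[a]), int(on[b])
            seg_scope = s[lo:hi + 1]
            seg_obj = in_object[lo:hi + 1, m] & seg_scope
            if not seg_obj.any():
                continue
            labels = _labels_from_object(seg_obj)
            entry = N_TERMINUS if lo == 0 else PENDING
            exit_ = N_TERMINUS if hi == T - 1 else PENDING
            paths.append(RawPath(
                path_id=pid, molecule_id=int(molecule_ids[m]),
                frames=frame_indices[lo:hi + 1],
                coords=coords[lo:hi + 1, m, :],
                labels=labels, entry_terminus=entry, exit_terminus=exit_))
            pid += 1
    return paths


def _labels_from_object(in_obj: np.ndarray) -> np.ndarray:
    obj_idx = np.flatnonzero(in_obj)
    first, last = obj_idx[0], obj_idx[-1]
    labels = np.full(len(in_obj), REENTRY, dtype=np.int8)
    labels[:first] = INCOMING
    labels[last + 1:] = OUTGOING
    labels[in_obj] = OBJECT
    return labels


def segment_path(path: RawPath) -> RawPath:
    """Recompute incoming/outgoing/re-entry labels from the object samples.

    The partition is exhaustive and disjoint: samples before the first
    object visit are incoming, after the last are outgoing, non-object
    samples between object visits are re-entry.
    """
    return replace(path, labels=_labels_from_object(path.labels == OBJECT))


def detect_inlets(paths: Sequence[RawPath]) -> list[Inlet]:
    """Surface inlets of already-trimmed paths (N termini yield none)."""
    inlets: list[Inlet] = []
    for p in paths:
        if p.n_samples == 0:
            continue
        if p.entry_terminus != N_TERMINUS:
            inlets.append(Inlet(tuple(map(float, p.coords[0])),
                                int(p.frames[0]), "entry", p.path_id))
        if p.exit_terminus != N_TERMINUS:
            inlets.append(Inlet(tuple(map(float, p.coords[-1])),
                                int(p.frames[-1]), "exit", p.path_id))
    return inlets


def trim_paths(paths: Sequence[RawPath], frames: FrameSeries,
               topology: Topology,
               barber_selection: Selection | None = None,
               min_radius: float = 0.5,
               vdw_correction: bool = True) -> list[RawPath]:
    """Apply the Auto-Barber trim to every crossing terminus of each path.

    The cutting sphere for a crossing uses the protein coordinates of the
    crossing's own frame.  With ``vdw_correction=False`` the nearest-atom
    distance is used without subtracting the vdW radius.
    """
    if barber_selection is None:
        prot_idx = np.flatnonzero(topology.protein_mask)
    else:
        prot_idx = topology.atom_indices(barber_selection.atom_ids)
    if prot_idx.size == 0:
        raise ValueError("barber selection resolves to no protein atoms")
    vdw = topology.vdw_radii[prot_idx] if vdw_correction else \
        np.zeros(prot_idx.size)
    frame_pos = {int(f): i for i, f in enumerate(frames.frame_indices)}

    def protein_coords(frame: int) -> np.ndarray:
        return frames.coords[frame_pos[frame], prot_idx, :].astype(float)

    trimmed: list[RawPath] = []
    for p in paths:
        q = p
        if q.entry_terminus != N_TERMINUS and q.n_samples:
            q = barber_trim(q, [q.coords[0]], protein_coords(int(q.frames[0])),
                            vdw, min_radius)
        if q.exit_terminus != N_TERMINUS and q.n_samples:
            q = barber_trim(q, [q.coords[-1]], protein_coords(int(q.frames[-1])),
                            vdw, min_radius)
        trimmed.append(q)
    return trimmed
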