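"""Tracked region ("object") and tracking limits ("scope").

The *object* is the region a molecule must visit to be traced — by default
a single sphere of given radius centred on the centre of geometry of the
active-site residues, recomputed every frame.  The *scope* limits tracing
to the protein interior, represented as the convex hull of a point
selection (Cα atoms by default), also recomputed per frame; the hull is
closed, i.e. boundary points count as inside.

`barber_trim` implements an Auto-Barber-style surface correction: paths
obtained with the crude convex-hull scope are trimmed back to an
approximated molecular surface by cutting spheres anchored at the scope
crossing points, sized by the distance to the nearest protein atom minus
that atom's van der Waals radius.  The nearest-atom-sphere rule is a
reconstruction of the published behaviour (the original description states
only that paths are trimmed to the surface using all protein atoms with
vdW correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .io import Topology

if TYPE_CHECKING:  # pragma: no cover
    from .tracking import RawPath

__all__ = ["SphereSet", "ConvexScope", "build_object", "in_object",
           "build_scope", "barber_trim"]


@dataclass
class SphereSet:
    """A union of spheres; membership is inside-or-on any sphere."""

    centers: np.ndarray  # (k, 3) Å
    radii: np.ndarray    # (k,) Å

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if len(self.radii) != len(self.centers):
            raise ValueError("one radius per center required")
        if np.any(self.radii <= 0):
            raise ValueError("all sphere radii must be > 0")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorised membership test; accepts (3,) or (n, 3) input."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((pts[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        inside = (d2 <= self.radii[None, :] ** 2).any(axis=1)
        return inside if np.asarray(points).ndim == 2 else bool(inside[0])


class ConvexScope:
    """Closed convex hull of a point set with a fast membership test.

    Membership uses the hull's half-space equations with two spherical
    prefilters (inscribed / circumscribed radius around the hull centroid)
    so that points far from the boundary skip the facet test.
    """

    def __init__(self, points: np.ndarray, tol: float = 1e-9):
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3 or len(points) < 4:
            raise ValueError("scope needs >= 4 three-dimensional points")
        try:
            self._hull = ConvexHull(points)
        except QhullError as err:
            raise ValueError(f"degenerate scope point set: {err}") from err
        self.tol = float(tol)
        self.points = points
        eq = self._hull.equations  # facet normals A, offsets b: A·x + b <= 0 inside
        self._A = eq[:, :3]
        self._b = eq[:, 3]
        self.centroid = points[self._hull.vertices].mean(axis=0)
        # largest sphere about the centroid certainly inside the hull
        self._r_in = -(self._A @ self.centroid + self._b).max()
        self._r_out = np.linalg.norm(
            points[self._hull.vertices] - self.centroid, axis=1).max()

    @property
    def vertices(self) -> np.ndarray:
        return self.points[self._hull.vertices]

    @property
    def volume(self) -> float:
        return float(self._hull.volume)

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.linalg.norm(pts - self.centroid, axis=1)
        inside = r <= self._r_in
        unsure = ~inside & (r <= self._r_out + self.tol)
        if np.any(unsure):
            vals = pts[unsure] @ self._A.T + self._b
            inside[unsure] = (vals <= self.tol).all(axis=1)
        return inside if np.asarray(points).ndim == 2 else bool(inside[0])


def build_object(topology: Topology, frame_coords: np.ndarray,
                 object_residues: Sequence[int], radius: float = 4.0,
                 atoms: str = "all") -> SphereSet:
    """One sphere at the centre of geometry of the listed residues.

    ``atoms`` selects which atoms enter the centre of geometry: ``"all"``
    (default) or ``"CA"`` for alpha carbons only.  The object is meant to
    be rebuilt per frame (the active site moves with the protein).
    """
    if not len(object_residues):
        raise ValueError("object_residues must not be empty")
    if radius <= 0:
        raise ValueError("object radius must be > 0")
    mask = np.isin(topology.resids, np.asarray(list(object_residues)))
    if atoms == "CA":
        mask &= np.char.upper(topology.atom_names.astype(str)) == "CA"
    elif atoms != "all":
        raise ValueError("atoms must be 'all' or 'CA'")
    if not mask.any():
        raise ValueError(f"no atoms found for residues {list(object_residues)}")
    center = np.asarray(frame_coords, dtype=float)[mask].mean(axis=0)
    return SphereSet(center[None, :], np.array([radius]))


def in_object(point: np.ndarray, obj: SphereSet):
    """True iff the point lies inside-or-on any object sphere."""
    return obj.contains(point)


def build_scope(scope_points: np.ndarray, tol: float = 1e-9) -> ConvexScope:
    """Convex hull of the scope selection (raises on degenerate input)."""
    return ConvexScope(scope_points, tol=tol)


def barber_trim(path: "RawPath", crossings: Sequence[np.ndarray],
                protein_coords: np.ndarray, protein_vdw: np.ndarray,
                min_radius: float = 0.5) -> "RawPath":
    """Trim a path's incoming head and outgoing tail to the surface.

    For each scope-boundary crossing point a cutting sphere is centred at
    the crossing with radius ``max(d_nearest_atom - vdw_nearest, min_radius)``.
    Leading incoming samples and trailing outgoing samples strictly inside
    any cutting sphere are dropped; object (and re-entry) samples are never
    removed.  Trimming with the same crossings is idempotent.
    """
    from .tracking import OBJECT  # local import to avoid a cycle

    crossings = [np.asarray(c, dtype=float) for c in crossings]
    if not crossings or path.n_samples == 0:
        return path
    protein_coords = np.asarray(protein_coords, dtype=float)
    if len(protein_coords) == 0:
        raise ValueError("protein atom set must not be empty")
    tree = cKDTree(protein_coords)
    centers = np.asarray(crossings)
    dist, idx = tree.query(centers)
    radii = np.maximum(dist - np.asarray(protein_vdw, dtype=float)[idx],
                       min_radius)

    obj_idx = np.flatnonzero(path.labels == OBJECT)
    first_obj, last_obj = int(obj_idx[0]), int(obj_idx[-1])

    def inside_any(p: np.ndarray) -> bool:
        return bool((np.linalg.norm(centers - p, axis=1) < radii).any())

    start = 0
    while start < first_obj and inside_any(path.coords[start]):
        start += 1
    stop = path.n_samples
    while stop - 1 > last_obj and inside_any(path.coords[stop - 1]):
        stop -= 1
    if start == 0 and stop == path.n_samples:
        return path
    return path.slice(start, stop)
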