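"""Object spheres, convex-hull scope (vs an LP oracle) and Auto-Barber."""

import numpy as np
import pytest
from scipy.optimize import linprog

from soltrack import SphereSet, build_object, build_scope, in_object
from soltrack.regions import barber_trim
from soltrack.io import Topology

from conftest import path_from_pattern


def lp_hull_member(points, query, tol=1e-9):
    """Convex-combination feasibility: query = P^T λ, λ ≥ 0, Σλ = 1."""
    n = len(points)
    A_eq = np.vstack([points.T, np.ones(n)])
    b_eq = np.append(query, 1.0)
    res = linprog(np.zeros(n), A_eq=A_eq, b_eq=b_eq, bounds=(0, None),
                  method="highs")
    return res.status == 0


def simple_topology(coords, resids=None):
    n = len(coords)
    resids = np.arange(1, n + 1) if resids is None else np.asarray(resids)
    return Topology(
        atom_ids=np.arange(1, n + 1),
        atom_names=np.array(["CA"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        resids=resids,
        resnames=np.array(["GLY"] * n, dtype=object),
        vdw_radii=np.full(n, 1.5),
    )


class TestBuildObject:
    def test_two_atom_residue_symmetry(self):
        topo = simple_topology(np.zeros((2, 3)), resids=[7, 7])
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        obj = build_object(topo, coords, [7], radius=3.0)
        np.testing.assert_allclose(obj.centers[0], [1, 0, 0])
        assert obj.radii[0] == 3.0

    def test_center_is_mean_of_all_member_atoms(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(15, 3))
        resids = np.repeat([105, 154, 235, 265, 300], 3)
        topo = simple_topology(coords, resids=resids)
        obj = build_object(topo, coords, [105, 154, 235, 265, 300], radius=4.0)
        # independent mean over the residue atoms
        np.testing.assert_allclose(obj.centers[0], coords.mean(axis=0),
                                   atol=1e-6)
        assert obj.radii[0] == 4.0

    def test_empty_residue_list_is_error(self):
        topo = simple_topology(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            build_object(topo, np.zeros((1, 3)), [], radius=4.0)


class TestInObject:
    def test_boundary_closed(self):
        obj = SphereSet(np.zeros((1, 3)), np.array([4.0]))
        assert in_object(np.array([0, 0, 3.9]), obj)
        assert not in_object(np.array([0, 0, 4.1]), obj)
        assert in_object(np.array([0, 0, 4.0]), obj)

    def test_matches_distance_formula(self):
        rng = np.random.default_rng(2)
        centers = rng.normal(size=(3, 3)) * 5
        radii = rng.random(3) * 3 + 0.5
        obj = SphereSet(centers, radii)
        pts = rng.normal(size=(500, 3)) * 8
        expected = np.array([
            any(np.linalg.norm(p - c) <= r for c, r in zip(centers, radii))
            for p in pts])
        np.testing.assert_array_equal(obj.contains(pts), expected)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        centers, radii = rng.normal(size=(2, 3)), np.array([1.5, 2.5])
        pts = rng.normal(size=(200, 3)) * 4
        shift = np.array([13.0, -7.0, 5.0])
        before = SphereSet(centers, radii).contains(pts)
        after = SphereSet(centers + shift, radii).contains(pts + shift)
        np.testing.assert_array_equal(before, after)


class TestConvexScope:
    def test_unit_cube(self):
        corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1)
                            for z in (0, 1)], dtype=float)
        scope = build_scope(corners)
        assert scope.contains(np.array([0.5, 0.5, 0.5]))
        assert not scope.contains(np.array([1.5, 0.0, 0.0]))
        # boundary counts as inside (closed hull)
        assert scope.contains(np.array([1.0, 0.5, 0.5]))

    def test_generating_points_are_members(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(50, 3))
        scope = build_scope(pts)
        assert scope.contains(pts).all()

    def test_degenerate_set_is_error(self):
        coplanar = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(ValueError, match="degenerate"):
            build_scope(coplanar)

    def test_agrees_with_lp_oracle(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(60, 3)) * 4
        scope = build_scope(pts)
        queries = rng.normal(size=(150, 3)) * 5
        ours = scope.contains(queries)
        oracle = np.array([lp_hull_member(pts, q) for q in queries])
        np.testing.assert_array_equal(ours, oracle)


class TestBarberTrim:
    def protein(self):
        # single pseudo-atom at origin, vdW 1.5
        return np.zeros((1, 3)), np.array([1.5])

    def test_cutting_radius_rule(self):
        # crossing 3.0 Å from the atom -> cutting radius 1.5 Å
        coords, vdw = self.protein()
        path = path_from_pattern("iiioo")
        # place head samples at known distances from the crossing
        crossing = np.array([3.0, 0.0, 0.0])
        path.coords[:] = [[3.0, 0, 0],     # at the crossing: removed
                          [3.0, 1.0, 0],   # 1.0 < 1.5 from crossing: removed
                          [3.0, 1.6, 0],   # 1.6 > 1.5: retained
                          [0.5, 0, 0], [0.6, 0, 0]]
        trimmed = barber_trim(path, [crossing], coords, vdw)
        assert trimmed.n_samples == 3
        np.testing.assert_allclose(trimmed.coords[0], [3.0, 1.6, 0])

    def test_min_radius_clamp(self):
        coords, vdw = self.protein()
        # crossing just outside the vdW surface: raw radius ~0, clamped to 0.5
        crossing = np.array([1.6, 0.0, 0.0])
        path = path_from_pattern("iio")
        path.coords[:] = [[1.6, 0, 0], [1.6, 0.4, 0], [0.2, 0, 0]]
        trimmed = barber_trim(path, [crossing], coords, vdw, min_radius=0.5)
        assert trimmed.n_samples == 1   # both head samples inside 0.5 Å sphere

    def test_object_samples_never_removed(self):
        coords, vdw = self.protein()
        path = path_from_pattern("ooo")
        path.coords[:] = [[3.0, 0, 0], [3.1, 0, 0], [3.2, 0, 0]]
        trimmed = barber_trim(path, [np.array([3.0, 0, 0])], coords, vdw)
        assert trimmed.n_samples == 3

    def test_idempotent_for_fixed_crossings(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(size=(20, 3)) * 3
        vdw = np.full(20, 1.5)
        path = path_from_pattern("iiiioogg")
        path.coords[:] = rng.normal(size=(8, 3)) * 4
        crossings = [path.coords[0].copy(), path.coords[-1].copy()]
        once = barber_trim(path, crossings, coords, vdw)
        twice = barber_trim(once, crossings, coords, vdw)
        assert once.n_samples == twice.n_samples
        np.testing.assert_array_equal(once.frames, twice.frames)

    def test_trimmed_endpoints_outside_vdw_spheres(self, one_channel_system,
                                                   one_channel_tracking):
        paths, _, _ = one_channel_tracking
        system = one_channel_system
        atoms = system.frames.coords[0][:system.n_protein_atoms].astype(float)
        vdw = system.topology.vdw_radii[:system.n_protein_atoms]
        for p in paths:
            for end in (p.coords[0], p.coords[-1]):
                d = np.linalg.norm(atoms - end, axis=1)
                assert np.all(d >= vdw - 1e-9)
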