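"""Density grids, pockets/cavities, hot-spots, wall residues, trapping."""

import numpy as np
import pytest

from soltrack import (DensityGrid, accumulate_density, derive_pockets,
                      detect_hotspots, trapped_molecules, wall_residues,
                      write_dx)
from soltrack.tracking import OBJECT, RawPath

from conftest import path_from_pattern


def sample_path(points, labels=None):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    lab = np.full(n, OBJECT) if labels is None else labels
    return RawPath(0, 1, np.arange(n), points, lab)


class TestAccumulateDensity:
    def test_single_sample_single_voxel(self):
        grid = accumulate_density([sample_path([[0.2, 0.3, 0.4]])], 1.0)
        assert grid.total == 1
        assert (grid.counts == 1).sum() == 1

    def test_seven_samples_one_voxel(self):
        pts = np.tile([[5.1, 5.2, 5.3]], (7, 1))
        grid = accumulate_density([sample_path(pts)], 1.0)
        assert grid.counts.max() == 7 and grid.total == 7

    def test_matches_histogram_oracle(self):
        rng = np.random.default_rng(0)
        pts = rng.random((5000, 3)) * 10
        grid = accumulate_density([sample_path(pts)], 1.0)
        # independent brute-force binning with identical edges
        edges = [np.arange(grid.origin[d],
                           grid.origin[d] + (grid.shape[d] + 0.5) * grid.spacing,
                           grid.spacing) for d in range(3)]
        oracle, _ = np.histogramdd(pts, bins=edges)
        np.testing.assert_array_equal(grid.counts, oracle.astype(int))

    def test_total_conserved_under_origin_shift(self):
        rng = np.random.default_rng(1)
        pts = rng.random((2000, 3)) * 8
        g1 = accumulate_density([sample_path(pts)], 1.0)
        g2 = accumulate_density([sample_path(pts + 0.37)], 1.0)
        assert g1.total == g2.total == 2000

    def test_segment_filter(self):
        p = path_from_pattern("iog")
        grid = accumulate_density([p], 1.0, segments=[OBJECT])
        assert grid.total == 1

    def test_empty_is_error(self):
        with pytest.raises(ValueError, match="empty grid"):
            accumulate_density([], 1.0)


class TestDerivePockets:
    def test_threshold_one_inner_equals_outer(self):
        rng = np.random.default_rng(2)
        grid = accumulate_density([sample_path(rng.random((500, 3)) * 5)], 1.0)
        outer, inner = derive_pockets(grid, inner_threshold=1)
        np.testing.assert_array_equal(outer.mask, inner.mask)
        assert outer.volume == inner.volume

    def test_two_blocks_two_components(self):
        counts = np.zeros((20, 5, 5), dtype=int)
        counts[1:4, 1:4, 1:4] = 1
        counts[15:18, 1:4, 1:4] = 1
        grid = DensityGrid(np.zeros(3), 1.0, counts)
        outer, _ = derive_pockets(grid, inner_threshold=1)
        assert len(outer.cavities) == 2
        assert [c.volume for c in outer.cavities] == [27.0, 27.0]
        # component volumes sum to pocket volume
        assert sum(c.volume for c in outer.cavities) == outer.volume

    def test_26_connectivity_joins_diagonal_voxels(self):
        counts = np.zeros((4, 4, 4), dtype=int)
        counts[0, 0, 0] = 1
        counts[1, 1, 1] = 1
        grid = DensityGrid(np.zeros(3), 1.0, counts)
        outer, _ = derive_pockets(grid, inner_threshold=1)
        assert len(outer.cavities) == 1

    def test_spherical_cavity_volume(self, closed_shell_system):
        """Solvent confined to a 6 Å cavity: inner volume near 4/3·π·6³."""
        from conftest import track_system
        paths, _, _ = track_system(closed_shell_system)
        grid = accumulate_density(paths, spacing=1.0)
        _, inner = derive_pockets(grid)
        analytic = 4 / 3 * np.pi * 6.0 ** 3
        assert abs(inner.volume - analytic) / analytic < 0.15
        assert len(inner.cavities) == 1


class TestHotspots:
    def test_gaussian_blob_single_hotspot_at_mode(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(loc=[2.0, -1.0, 3.0], scale=2.0, size=(20000, 3))
        grid = accumulate_density([sample_path(pts)], 1.0)
        spots = detect_hotspots(grid, percentile=95)
        assert len(spots) == 1
        mode = np.unravel_index(np.argmax(grid.counts), grid.shape)
        assert spots[0].voxel == tuple(int(v) for v in mode)

    def test_uniform_counts_no_hotspot(self):
        grid = DensityGrid(np.zeros(3), 1.0, np.full((6, 6, 6), 4))
        assert detect_hotspots(grid) == []

    def test_two_separated_blobs_two_hotspots(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(loc=[0, 0, 0], scale=1.5, size=(8000, 3)),
                         rng.normal(loc=[25, 0, 0], scale=1.5, size=(8000, 3))])
        grid = accumulate_density([sample_path(pts)], 1.0)
        assert len(detect_hotspots(grid, percentile=95)) == 2


class TestWallResidues:
    def topo_with_atoms(self, coords):
        from soltrack.io import Topology
        n = len(coords)
        return Topology(
            atom_ids=np.arange(1, n + 1),
            atom_names=np.array(["CA"] * n, dtype=object),
            elements=np.array(["C"] * n, dtype=object),
            resids=np.arange(1, n + 1),
            resnames=np.array(["GLY"] * n, dtype=object),
            vdw_radii=np.full(n, 1.7),
        ), np.asarray(coords, dtype=float)

    def test_cutoff_inclusion_and_exclusion(self):
        grid = DensityGrid(np.zeros(3), 1.0, np.ones((1, 1, 1), dtype=int))
        # voxel center at (0.5, 0.5, 0.5)
        topo, coords = self.topo_with_atoms([[3.5, 0.5, 0.5], [6.5, 0.5, 0.5]])
        res = wall_residues(np.array([[0, 0, 0]]), grid, topo, [coords], 4.5)
        assert res == [1]    # atom 1 at 3.0 Å in, atom 2 at 6.0 Å out

    def test_toy_cavity_walls_are_inner_shell(self, closed_shell_system):
        """Cavity wall residues are exactly the pseudo-atoms near the wall."""
        from conftest import track_system
        system = closed_shell_system
        paths, _, _ = track_system(system)
        grid = accumulate_density(paths, spacing=1.0)
        _, inner = derive_pockets(grid)
        cav = inner.cavities[0]
        frame0 = system.frames.coords[0]
        res = wall_residues(cav.voxels, grid, system.topology, [frame0], 4.5)
        # expected: protein atoms within 4.5 Å of any cavity voxel center
        centers = grid.voxel_centers(cav.voxels)
        prot = frame0[:system.n_protein_atoms].astype(float)
        d = np.linalg.norm(prot[:, None, :] - centers[None], axis=2).min(axis=1)
        expected = sorted(int(r) for r in
                          system.topology.resids[:system.n_protein_atoms][d <= 4.5])
        assert res == expected
        assert len(res) > 0


class TestTrapped:
    def region_grid(self):
        grid = DensityGrid(np.zeros(3), 1.0, np.ones((40, 3, 3), dtype=int))
        region = np.array([[i, 0, 0] for i in range(40)])
        return grid, region

    def test_hand_counted_dwell(self):
        grid, region = self.region_grid()
        # 30 samples idling in the region voxel row before the object
        coords = np.vstack([np.tile([[5.5, 0.5, 0.5]], (30, 1)),
                            [[200.0, 200, 200]]])   # object sample elsewhere
        labels = np.array([0] * 30 + [OBJECT], dtype=np.int8)
        p = RawPath(0, 1, np.arange(31), coords, labels)
        report = trapped_molecules([p], 20.0, region, grid, dt_ps=1.0)
        assert len(report) == 1
        assert report.iloc[0]["dwell_ps"] == 30.0
        assert report.iloc[0]["where"] == "before_object"

    def test_single_frame_crossing_not_reported(self):
        grid, region = self.region_grid()
        coords = np.array([[5.5, 0.5, 0.5], [200.0, 200, 200]])
        p = RawPath(0, 1, np.arange(2), coords,
                    np.array([0, OBJECT], dtype=np.int8))
        report = trapped_molecules([p], 2.0, region, grid, dt_ps=1.0)
        assert report.empty

    def test_empty_region_empty_report(self):
        grid, _ = self.region_grid()
        p = path_from_pattern("iog")
        report = trapped_molecules([p], 1.0, np.empty((0, 3)), grid)
        assert report.empty


def test_dx_writer_round_trips_header(tmp_path):
    grid = DensityGrid(np.array([1.0, 2.0, 3.0]), 0.5,
                       np.arange(8).reshape(2, 2, 2))
    out = tmp_path / "d.dx"
    write_dx(grid, out)
    text = out.read_text()
    assert "gridpositions counts 2 2 2" in text
    assert "items 8 data follows" in text
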