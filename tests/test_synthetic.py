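"""Toy system generator: geometry, dynamics, determinism, toy MSAs."""

import numpy as np
import pytest

from soltrack import (ToySystemSpec, entropy_profile, make_toy_msa,
                      make_toy_protein, make_toy_system, simulate_solvent,
                      schneider_entropy)


class TestToyProtein:
    def test_closed_shell_keeps_all_lattice_points(self):
        spec = ToySystemSpec(channels=[])
        protein = make_toy_protein(spec)
        radii = np.linalg.norm(protein.coords, axis=1)
        assert radii.min() >= spec.inner_radius - 1e-5
        assert radii.max() <= spec.shell_outer_radius + 1e-5

    def test_channel_clears_the_bore(self):
        spec = ToySystemSpec(channels=[((0, 0, 1), 4.0)])
        protein = make_toy_protein(spec)
        pts = protein.coords.astype(float)
        lateral = np.linalg.norm(pts[:, :2], axis=1)
        on_channel_side = pts[:, 2] > 0
        assert not np.any(on_channel_side & (lateral < 4.0))
        # the opposite side is intact
        assert np.any(~on_channel_side & (lateral < 4.0))

    def test_one_atom_per_residue(self):
        protein = make_toy_protein(ToySystemSpec())
        topo = protein.topology
        assert len(np.unique(topo.resids)) == topo.n_atoms
        assert np.all(topo.protein_mask)

    def test_excessive_channels_error(self):
        with pytest.raises(ValueError, match="half of the shell"):
            make_toy_protein(ToySystemSpec(
                channels=[((0, 0, 1), 40.0), ((0, 0, -1), 40.0)]))

    def test_deterministic(self):
        a = make_toy_protein(ToySystemSpec(channels=[((1, 0, 0), 4.0)]))
        b = make_toy_protein(ToySystemSpec(channels=[((1, 0, 0), 4.0)]))
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_mouth_ground_truth_on_axis(self):
        spec = ToySystemSpec(channels=[((0, 1, 0), 4.0)])
        gt = make_toy_protein(spec).ground_truth
        np.testing.assert_allclose(gt.mouth_centers[0],
                                   [0, spec.inner_radius, 0])
        assert gt.cavity_volume == pytest.approx(4 / 3 * np.pi * 6 ** 3)


class TestSimulateSolvent:
    def test_same_seed_bit_identical(self):
        spec = ToySystemSpec(n_particles=10, n_frames=50, seed=42)
        a = make_toy_system(spec)
        b = make_toy_system(ToySystemSpec(n_particles=10, n_frames=50, seed=42))
        np.testing.assert_array_equal(a.frames.coords, b.frames.coords)

    def test_different_seed_differs(self):
        a = make_toy_system(ToySystemSpec(n_particles=10, n_frames=50, seed=1))
        b = make_toy_system(ToySystemSpec(n_particles=10, n_frames=50, seed=2))
        assert not np.array_equal(a.frames.coords, b.frames.coords)

    def test_step_zero_frames_identical(self):
        spec = ToySystemSpec(n_particles=5, n_frames=20, step_size=1e-12,
                             seed=3)
        system = make_toy_system(spec)
        solvent = system.frames.coords[:, system.n_protein_atoms:, :]
        assert np.abs(solvent - solvent[0]).max() < 1e-9

    def test_closed_shell_confines_particles(self, closed_shell_system):
        system = closed_shell_system
        solvent = system.frames.coords[:, system.n_protein_atoms:, :]
        radii = np.linalg.norm(solvent.astype(float), axis=2)
        assert radii.max() < system.spec.inner_radius

    def test_hard_core_respected(self, closed_shell_system):
        system = closed_shell_system
        from scipy.spatial import cKDTree
        atoms = system.frames.coords[0][:system.n_protein_atoms].astype(float)
        tree = cKDTree(atoms)
        solvent = system.frames.coords[::100, system.n_protein_atoms:, :]
        d = tree.query(solvent.reshape(-1, 3))[0]
        assert d.min() >= system.spec.clearance - 1e-6

    def test_channel_crossings_near_mouth(self, one_channel_system):
        """Particles escape; scope crossings lie within the mouth disc + 1 Å."""
        system = one_channel_system
        spec = system.spec
        solvent = system.frames.coords[:, system.n_protein_atoms:, :].astype(float)
        radii = np.linalg.norm(solvent, axis=2)
        outside = radii > spec.shell_outer_radius
        assert outside.any()          # at least one particle exits
        # frames where a particle transitions from inside to outside the wall
        trans = ~outside[:-1] & outside[1:]
        t_idx, m_idx = np.nonzero(trans)
        crossing = solvent[t_idx, m_idx]   # last inside position
        lateral = np.linalg.norm(crossing[:, :2], axis=1)
        bore = spec.channels[0][1]
        assert np.all(lateral <= bore + 1.0)
        assert np.all(crossing[:, 2] > 0)


class TestToyMSA:
    def test_near_zero_concentration_single_letter(self):
        msa, planted = make_toy_msa(40, 30, 10,
                                    concentrations=(1e-9, 5.0), seed=9)
        for j in planted:
            assert len(set(msa.column(j))) == 1

    def test_single_sequence_zero_entropy(self):
        msa, _ = make_toy_msa(1, 25, 5, seed=10)
        prof = entropy_profile(msa)
        np.testing.assert_allclose(prof.values, 0.0)

    def test_planted_columns_less_entropic(self):
        for seed in range(10):
            msa, planted = make_toy_msa(100, 60, 10, seed=seed)
            prof = entropy_profile(msa)
            rest = np.setdiff1d(np.arange(60), planted)
            assert (prof.values[planted].mean()
                    < prof.values[rest].mean())

    def test_deterministic_per_seed(self):
        a, pa = make_toy_msa(20, 15, 4, seed=11)
        b, pb = make_toy_msa(20, 15, 4, seed=11)
        assert a.rows == b.rows and pa == pb


def test_end_to_end_three_channel_recovery():
    """Full chain on an asymmetric 3-channel toy: clusters at the mouths,
    wide channel carries more inlets than the narrow one, largest flux cell
    on the diagonal, cavity volume near analytic."""
    import soltrack as st
    from conftest import track_system

    spec = ToySystemSpec(
        channels=[((0, 0, 1), 5.0), ((1, 0, 0), 4.0), ((0, 1, 0), 3.2)],
        n_particles=50, n_frames=12000, seed=17)
    system = make_toy_system(spec)
    paths, inlets, clusters = track_system(system)
    assert len(clusters.sizes) == 3
    mouths = system.ground_truth.mouth_centers
    for name, c in clusters.centroids.items():
        assert np.linalg.norm(mouths - c, axis=1).min() < 2.0

    ft = st.flux_table(paths, clusters)
    shares = ft.inlet_shares()
    # wider channel mouth collects a larger inlet share than the narrowest
    by_mouth = {}
    for name, c in clusters.centroids.items():
        by_mouth[int(np.argmin(np.linalg.norm(mouths - c, axis=1)))] = name
    assert shares[by_mouth[0]] > shares[by_mouth[2]]

    # largest cluster-to-cluster flux cell sits on the diagonal
    sub = ft.counts.loc[clusters.cluster_names, clusters.cluster_names]
    arr = sub.to_numpy()
    i, j = np.unravel_index(np.argmax(arr), arr.shape)
    assert i == j

    grid = st.accumulate_density(paths, spacing=1.0)
    _, inner = st.derive_pockets(grid)
    analytic = system.ground_truth.cavity_volume
    assert abs(inner.cavities[0].volume - analytic) / analytic < 0.15
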