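import numpy as np
import pytest

from vibronet import synthetic as syn
from vibronet.constants import omega_to_wavenumber


class TestHarmonicGenerator:
    def test_single_oscillator_restates_frequency(self):
        spec = syn.SyntheticSpec(n_frames=64, dt=100.0, seed=0)
        masses = np.array([12.0])
        K = syn.stiffness_for_frequencies([50.0], masses)
        _, truth = syn.generate_harmonic_trajectory(spec, K, masses)
        assert truth.mode_frequencies == pytest.approx([50.0])

    def test_zero_stiffness_free_particles_constant_velocity(self):
        spec = syn.SyntheticSpec(n_frames=32, dt=100.0, seed=0)
        masses = np.ones(2)
        traj, truth = syn.generate_harmonic_trajectory(spec, np.zeros((6, 6)), masses)
        assert truth.mode_frequencies == []
        assert np.ptp(traj.velocities, axis=0).max() < 1e-14

    def test_three_bead_chain_matches_dense_eigensolve_oracle(self):
        k, m = 0.5, 2.0
        masses = np.full(3, m)
        spec = syn.SyntheticSpec(n_frames=16, seed=0)
        K = syn.chain_stiffness_1d(3, k)
        _, truth = syn.generate_harmonic_trajectory(spec, K, masses)
        # oracle: dense eigensolve of the 1-D 3x3 dynamical matrix
        D = (
            np.array([[k, -k, 0.0], [-k, 2 * k, -k], [0.0, -k, k]]) / m
        )
        w2 = np.sort(np.linalg.eigvalsh(D))
        expected = sorted(omega_to_wavenumber(np.sqrt(x)) for x in w2[1:])
        assert truth.mode_frequencies == pytest.approx(expected, rel=1e-10)
        # and the analytic chain frequencies sqrt(k/m), sqrt(3k/m)
        analytic = sorted(
            omega_to_wavenumber(np.sqrt(x)) for x in (k / m, 3 * k / m)
        )
        assert truth.mode_frequencies == pytest.approx(analytic, rel=1e-10)

    def test_rejects_asymmetric_and_indefinite_stiffness(self):
        spec = syn.SyntheticSpec(n_frames=4, seed=0)
        bad = np.zeros((3, 3))
        bad[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            syn.generate_harmonic_trajectory(spec, bad, np.ones(1))
        with pytest.raises(ValueError, match="negative eigenvalue"):
            syn.generate_harmonic_trajectory(spec, -np.eye(3), np.ones(1))

    def test_energy_conserved_to_machine_precision(self):
        spec = syn.SyntheticSpec(n_frames=256, dt=100.0, seed=4, velocity_scale=0.02)
        masses = np.array([12.0, 1.0])
        K = syn.stiffness_for_frequencies([30.0, 90.0], masses)
        traj, truth = syn.generate_harmonic_trajectory(spec, K, masses)
        m = np.repeat(masses, 3)
        x = traj.coords.reshape(len(traj.coords), -1)
        v = traj.velocities.reshape(len(traj.coords), -1)
        E = 0.5 * (v**2 * m).sum(axis=1) + 0.5 * np.einsum("ti,ij,tj->t", x, K, x)
        assert np.ptp(E) < 1e-12 * max(E.mean(), 1e-30)

    def test_bit_reproducible_given_seed(self):
        spec = syn.SyntheticSpec(n_frames=32, seed=9)
        masses = np.ones(2)
        K = syn.stiffness_for_frequencies([40.0], masses)
        t1, _ = syn.generate_harmonic_trajectory(spec, K, masses)
        t2, _ = syn.generate_harmonic_trajectory(spec, K, masses)
        assert np.array_equal(t1.coords, t2.coords)
        assert np.array_equal(t1.velocities, t2.velocities)


class TestTelegraphGenerator:
    def test_symmetric_rates_give_half_occupancy(self):
        spec = syn.SyntheticSpec(n_frames=50000, dt=100.0, seed=0)
        _, truth = syn.generate_hbond_telegraph(spec, 5e-4, 5e-4)
        occ = truth.extras["states"].mean()
        # 3 standard errors with the integrated autocorrelation correction
        rho = np.exp(-1e-3 * spec.dt)
        se = np.sqrt(0.25 / spec.n_frames * (1 + rho) / (1 - rho))
        assert abs(occ - 0.5) < 3 * se

    def test_occupancy_converges_to_rate_ratio(self):
        spec = syn.SyntheticSpec(n_frames=50000, dt=100.0, seed=1)
        k_on, k_off = 9e-4, 3e-4
        _, truth = syn.generate_hbond_telegraph(spec, k_on, k_off)
        p = k_on / (k_on + k_off)
        rho = np.exp(-(k_on + k_off) * spec.dt)
        se = np.sqrt(p * (1 - p) / spec.n_frames * (1 + rho) / (1 - rho))
        assert abs(truth.extras["states"].mean() - p) < 3 * se

    def test_invalid_rates_rejected(self):
        spec = syn.SyntheticSpec(n_frames=10, dt=100.0, seed=0)
        with pytest.raises(ValueError):
            syn.generate_hbond_telegraph(spec, 0.02, 1e-3)
        with pytest.raises(ValueError):
            syn.generate_hbond_telegraph(spec, -1e-3, 1e-3)

    def test_geometry_follows_hidden_state(self):
        spec = syn.SyntheticSpec(n_frames=200, dt=100.0, seed=3)
        traj, truth = syn.generate_hbond_telegraph(spec, 1e-3, 1e-3)
        states = truth.extras["states"][0]
        d_da = np.linalg.norm(traj.coords[:, 0] - traj.coords[:, 2], axis=1)
        assert np.array_equal(d_da < 3.5, states.astype(bool))


class TestFragmentSwitchGenerator:
    def test_coupling_one_is_deterministic_function_of_global(self, fragment_switch_run):
        _, truth = fragment_switch_run
        fs = truth.extras["fragment_states"]
        g = truth.extras["global_states"]
        assert np.array_equal(fs[0], g)  # coupling 1.0

    def test_coupling_zero_independent_of_global(self, fragment_switch_run):
        _, truth = fragment_switch_run
        fs = truth.extras["fragment_states"]
        g = truth.extras["global_states"]
        match = (fs[2] == g).mean()  # coupling 0.0 → expect 1/2
        assert abs(match - 0.5) < 3 / np.sqrt(len(g))

    def test_chain_has_no_breaks(self, fragment_switch_run):
        traj, _ = fragment_switch_run
        consec = np.linalg.norm(np.diff(traj.coords, axis=1), axis=-1)
        assert consec.max() < 4.5

    def test_out_of_chain_fragment_rejected(self):
        spec = syn.SyntheticSpec(n_frames=10, n_residues=20, seed=0)
        with pytest.raises(IndexError):
            syn.generate_fragment_switch_trajectory(spec, fragments=[(18, 1.0)])


class TestMSAGenerator:
    def test_planted_mi_close_to_analytic(self):
        from vibronet import coevolution as co

        spec = syn.SyntheticSpec(n_sequences=500, n_columns=10, seed=5)
        msa, truth = syn.generate_msa(spec, planted_pairs=[(1, 7, 1.0)])
        analytic = truth.extras["pair_tables"]["1,7"]["analytic_mi"]
        mi = co.msa_mi(msa, pseudocount=0.0)
        # plug-in MI bias ~ (K−1)/2N for K occupied cells, plus sampling noise
        assert abs(mi[1, 7] - analytic) < 0.1

    def test_zero_coupling_indistinguishable_from_shuffled_null(self):
        from vibronet import coevolution as co

        spec = syn.SyntheticSpec(n_sequences=300, n_columns=12, seed=6)
        msa, _ = syn.generate_msa(spec, planted_pairs=[(2, 9, 0.0)])
        mi = co.msa_mi(msa, pseudocount=0.0)
        rng = np.random.default_rng(0)
        null_max = []
        codes = msa.codes.copy()
        for _ in range(50):
            shuf = np.stack([rng.permutation(codes[:, c]) for c in range(12)], axis=1)
            null_mi = co.msa_mi(co.WeightedMSA(codes=shuf, ids=msa.ids), pseudocount=0.0)
            iu = np.triu_indices(12, 1)
            null_max.append(null_mi[iu].max())
        iu = np.triu_indices(12, 1)
        assert mi[iu].max() <= np.quantile(null_max, 0.99) * 1.1

    def test_redundant_cluster_weights_sum_to_one(self):
        from vibronet import coevolution as co

        spec = syn.SyntheticSpec(n_sequences=30, n_columns=50, seed=7)
        msa, truth = syn.generate_msa(spec, redundancy=[(0, 10, 0.02)])
        w = co.sequence_weights(msa, identity_threshold=0.62)
        labels = np.asarray(truth.extras["cluster_labels"])
        cluster0 = w[labels == 0]
        assert len(cluster0) == 11
        assert cluster0.sum() == pytest.approx(1.0)

    def test_rejects_bad_coupling_and_overlapping_pairs(self):
        spec = syn.SyntheticSpec(n_sequences=10, n_columns=10, seed=0)
        with pytest.raises(ValueError):
            syn.generate_msa(spec, planted_pairs=[(0, 1, 1.5)])
        with pytest.raises(ValueError):
            syn.generate_msa(spec, planted_pairs=[(0, 1, 0.5), (1, 2, 0.5)])


class TestTwoDomainGenerator:
    def test_truth_hinge_is_linker_by_construction(self):
        _, truth = syn.generate_two_domain_elastic(20, 3, seed=0)
        assert truth.hinge_residues == [20, 21, 22]

    def test_zero_linker_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_two_domain_elastic(20, 0)
        with pytest.raises(ValueError):
            syn.generate_two_domain_elastic(3, 2)

    def test_reproducible_given_seed(self):
        a, _ = syn.generate_two_domain_elastic(15, 2, seed=3)
        b, _ = syn.generate_two_domain_elastic(15, 2, seed=3)
        assert np.array_equal(a.coords, b.coords)
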