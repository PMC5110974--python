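import numpy as np
import pytest

from vibronet import hbonds as hb
from vibronet import synthetic as syn
from vibronet.trajectory import Trajectory, select


def _frame(d_ha, deviation_deg, d_dh=1.0):
    """Donor at origin, hydrogen at (d_dh, 0, 0), acceptor placed so the
    H···A distance is ``d_ha`` and the D–H···A deviation from linearity is
    ``deviation_deg``."""
    D = np.array([0.0, 0.0, 0.0])
    H = np.array([d_dh, 0.0, 0.0])
    dev = np.radians(deviation_deg)
    A = H + d_ha * np.array([np.cos(dev), np.sin(dev), 0.0])
    return np.stack([D, H, A])


class TestCriterion:
    def test_all_criteria_satisfied(self):
        frame = _frame(1.9, 15.0)  # D–A 2.88 Å, H···A 1.9 Å, deviation 15°
        bonds = hb.detect_hbonds(frame, donors=[(0, 1)], acceptors=[2])
        assert bonds == [(0, 1, 2)]

    def test_distance_exactly_at_limit_is_absent(self):
        frame = _frame(2.5, 0.0)  # linear, D–A exactly 3.5 Å
        assert np.linalg.norm(frame[2] - frame[0]) == pytest.approx(3.5)
        assert hb.detect_hbonds(frame, [(0, 1)], [2]) == []

    def test_oh_distance_above_limit_absent(self):
        # D–A 3.0 Å with H off-axis so H···A is 2.7 Å
        D = np.array([0.0, 0.0, 0.0])
        A = np.array([3.0, 0.0, 0.0])
        H = np.array([0.4517, 0.8922, 0.0])  # |DH| ≈ 1, |HA| ≈ 2.7
        frame = np.stack([D, H, A])
        assert np.linalg.norm(H - A) == pytest.approx(2.7, abs=0.01)
        assert hb.detect_hbonds(frame, [(0, 1)], [2]) == []

    def test_angle_above_limit_absent(self):
        frame = _frame(1.9, 35.0)  # distances fine, deviation 35°
        assert hb.detect_hbonds(frame, [(0, 1)], [2]) == []

    def test_donor_without_hydrogen_skipped_with_warning(self):
        frame = _frame(1.9, 0.0)
        with pytest.warns(UserWarning, match="no attached hydrogen"):
            bonds = hb.detect_hbonds(frame, [(0, None)], [2])
        assert bonds == []

    def test_donor_vertex_variant(self):
        frame = _frame(1.9, 10.0)
        crit = hb.HBondCriterion(angle_vertex="donor")
        assert hb.detect_hbonds(frame, [(0, 1)], [2], crit) == [(0, 1, 2)]


class TestExistenceMatrix:
    def test_matrix_reproduces_hidden_telegraph_states(self):
        spec = syn.SyntheticSpec(n_frames=500, dt=100.0, seed=8)
        traj, truth = syn.generate_hbond_telegraph(spec, 1e-3, 1e-3)
        mat = hb.existence_matrix(
            traj, truth.extras["donors"], truth.extras["acceptors"]
        )
        assert np.array_equal(mat.matrix[0], truth.extras["states"][0])

    def test_permanent_bond_all_ones_and_never_bond_excluded(self):
        on = _frame(1.9, 0.0)
        coords = np.stack([on, on, on])[None].reshape(3, 3, 3)
        traj = Trajectory.from_arrays(coords=coords, dt=1.0, elements=["O", "H", "O"])
        mat = hb.existence_matrix(traj, [(0, 1)], [2])
        assert mat.matrix.shape == (1, 3)
        assert mat.matrix.all()

    def test_empty_universe_warns(self):
        off = _frame(6.0, 0.0)
        traj = Trajectory.from_arrays(coords=off[None], dt=1.0, elements=["O", "H", "O"])
        with pytest.warns(UserWarning, match="no hydrogen bond"):
            mat = hb.existence_matrix(traj, [(0, 1)], [2])
        assert mat.n_bonds == 0


class TestAutocorrelation:
    def test_all_ones_matrix_constant_unity(self):
        mat = hb.HBondExistenceMatrix(
            bonds=[(0, 1, 2)], matrix=np.ones((1, 50), dtype=int), dt=100.0
        )
        corr = hb.hbond_autocorrelation(mat, max_lag_fs=2000.0)
        np.testing.assert_allclose(corr.values, 1.0)

    def test_alternating_series_parity(self):
        row = np.tile([1, 0], 50)
        mat = hb.HBondExistenceMatrix(bonds=[(0, 1, 2)], matrix=row[None], dt=1.0)
        corr = hb.hbond_autocorrelation(mat, max_lag_fs=6.0)
        np.testing.assert_allclose(corr.values[::2], 1.0, atol=0.05)
        np.testing.assert_allclose(corr.values[1::2], 0.0, atol=1e-12)

    def test_lag_zero_exactly_one_and_row_permutation_invariance(self, rng):
        m = (rng.random((5, 200)) < 0.4).astype(int)
        m[0, 0] = 1  # ensure non-empty
        mat = hb.HBondExistenceMatrix(bonds=[(i, i, i) for i in range(5)], matrix=m, dt=1.0)
        corr = hb.hbond_autocorrelation(mat)
        assert corr.values[0] == pytest.approx(1.0)
        perm = rng.permutation(5)
        mat2 = hb.HBondExistenceMatrix(
            bonds=[mat.bonds[i] for i in perm], matrix=m[perm], dt=1.0
        )
        np.testing.assert_allclose(
            corr.values, hb.hbond_autocorrelation(mat2).values, atol=1e-12
        )

    def test_telegraph_matches_closed_form(self):
        spec = syn.SyntheticSpec(n_frames=100000, dt=100.0, seed=3)
        traj, truth = syn.generate_hbond_telegraph(spec, 1e-3, 1e-3)
        mat = hb.existence_matrix(
            traj, truth.extras["donors"], truth.extras["acceptors"]
        )
        corr = hb.hbond_autocorrelation(mat, max_lag_fs=2000.0)
        k_sum = 2e-3
        analytic = 0.5 + 0.5 * np.exp(-k_sum * corr.lags)
        # binomial SE inflated by the integrated autocorrelation time
        rho = np.exp(-k_sum * spec.dt)
        se = np.sqrt(
            analytic * (1 - analytic + 1e-12) / corr.n_samples * (1 + rho) / (1 - rho)
        ) / 0.5
        dev = np.abs(corr.values - analytic)[1:]
        assert (dev < np.maximum(3 * se[1:], 1e-3)).all()

    def test_continuous_variant_never_exceeds_intermittent(self):
        rng = np.random.default_rng(0)
        m = (rng.random((3, 300)) < 0.6).astype(int)
        mat = hb.HBondExistenceMatrix(bonds=[(0, 0, 0)] * 3, matrix=m, dt=1.0)
        inter = hb.hbond_autocorrelation(mat, max_lag_fs=20.0)
        cont = hb.hbond_autocorrelation(mat, max_lag_fs=20.0, continuous=True)
        assert (cont.values <= inter.values + 1e-12).all()

    def test_empty_matrix_rejected(self):
        mat = hb.HBondExistenceMatrix(bonds=[], matrix=np.zeros((0, 10), dtype=int), dt=1.0)
        with pytest.raises(ValueError):
            hb.hbond_autocorrelation(mat)


class TestRelaxationFit:
    def test_recovers_telegraph_relaxation_within_ten_percent(self):
        spec = syn.SyntheticSpec(n_frames=100000, dt=100.0, seed=5)
        traj, truth = syn.generate_hbond_telegraph(spec, 1e-3, 1e-3)
        mat = hb.existence_matrix(
            traj, truth.extras["donors"], truth.extras["acceptors"]
        )
        corr = hb.hbond_autocorrelation(mat, max_lag_fs=5000.0)
        tau, _, _ = hb.fit_relaxation_time(corr)
        assert tau == pytest.approx(truth.extras["relaxation_time_fs"], rel=0.10)


class TestContactMap:
    def _pair_traj(self, distances):
        coords = np.zeros((len(distances), 2, 3))
        coords[:, 1, 0] = distances
        return Trajectory.from_arrays(coords=coords, dt=1.0, elements=["C", "C"])

    def test_fixed_distance_inside_and_outside_cutoff(self):
        traj = self._pair_traj([4.0, 4.0, 4.0])
        a = select(traj, "resid 0")
        b = select(traj, "resid 1")
        assert hb.contact_map(traj, a, b, 4.5)["frequency"].iloc[0] == 1.0
        assert hb.contact_map(traj, a, b, 3.5)["frequency"].iloc[0] == 0.0

    def test_oscillating_pair_half_frequency(self):
        d = np.tile([3.0, 6.0], 50)
        traj = self._pair_traj(d)
        a = select(traj, "resid 0")
        b = select(traj, "resid 1")
        freq = hb.contact_map(traj, a, b, 4.0)["frequency"].iloc[0]
        assert freq == pytest.approx(0.5, abs=1.0 / len(d))

    def test_cutoff_mandatory_and_positive(self, small_traj):
        a = select(small_traj, "resid 0-4")
        b = select(small_traj, "resid 5-9")
        with pytest.raises(ValueError):
            hb.contact_map(small_traj, a, b, -1.0)
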