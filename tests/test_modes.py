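import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from vibronet import modes as md
from vibronet import synthetic as syn
from vibronet.trajectory import Trajectory


class TestSuperpose:
    def test_identity_for_identical_sets(self, rng):
        pts = rng.normal(size=(6, 3))
        R, t, rmsd = md.superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-6)

    def test_rotated_copy_recovered(self, rng):
        pts = rng.normal(size=(5, 3))
        rot = Rotation.from_euler("xyz", [90, 30, -40], degrees=True)
        moved = pts @ rot.as_matrix().T + np.array([1.0, -2.0, 3.0])
        _, _, rmsd = md.superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_mirror_image_of_chiral_set_keeps_positive_rmsd(self, rng):
        # chiral 4-point set; brute-force rotation grid confirms the minimum
        pts = np.array(
            [[0.0, 0, 0], [1.5, 0, 0], [1.5, 1.5, 0], [1.0, 1.0, 2.0]]
        )
        mirror = pts * np.array([1.0, 1.0, -1.0])
        _, _, rmsd = md.superpose(mirror, pts)
        assert rmsd > 0.1
        rng2 = np.random.default_rng(0)
        brute = min(
            np.sqrt(
                (
                    (
                        (mirror - mirror.mean(0)) @ Rotation.random(random_state=rng2).as_matrix().T
                        - (pts - pts.mean(0))
                    )
                    ** 2
                ).sum(axis=1).mean()
            )
            for _ in range(2000)
        )
        assert rmsd <= brute + 1e-6

    def test_collinear_and_tiny_sets_rejected(self):
        line = np.stack([np.arange(4.0), np.zeros(4), np.zeros(4)], axis=1)
        with pytest.raises(ValueError, match="collinear"):
            md.superpose(line, line)
        with pytest.raises(ValueError):
            md.superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestPCA:
    def test_single_direction_displacement_gives_pc1(self, rng):
        base = rng.normal(size=(5, 3)) * 4
        direction = np.zeros((5, 3))
        direction[2] = [1.0, 0.0, 0.0]
        amps = rng.normal(size=40)
        coords = base[None] + amps[:, None, None] * direction[None]
        traj = Trajectory.from_arrays(coords=coords, dt=1.0)
        model = md.pca_matrix(coords.reshape(40, -1))
        u = direction.ravel() / np.linalg.norm(direction)
        assert abs(model.eigenvectors[:, 0] @ u) > 1 - 1e-10
        assert model.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)
        assert traj.n_frames == 40

    def test_isotropic_cloud_eigenvalues_within_ten_percent(self, rng):
        data = rng.normal(size=(10000, 9))
        model = md.pca_matrix(data)
        assert model.eigenvalues[0] / model.eigenvalues[2] < 1.10

    def test_eigenvalue_sum_equals_covariance_trace(self, rng):
        data = rng.normal(size=(200, 12)) * rng.uniform(0.5, 2.0, 12)
        model = md.pca_matrix(data)
        trace = np.var(data, axis=0).sum()
        assert model.eigenvalues.sum() == pytest.approx(trace, rel=1e-10)

    def test_projections_on_distinct_modes_uncorrelated(self, rng):
        data = rng.normal(size=(500, 6)) @ rng.normal(size=(6, 6))
        model = md.pca_matrix(data)
        cov = np.cov(model.projections[:, 0], model.projections[:, 1])[0, 1]
        assert abs(cov) < 1e-8 * model.eigenvalues[0]

    def test_mode_truncation_warns(self, small_traj):
        with pytest.warns(UserWarning, match="truncating"):
            md.pca(small_traj, n_modes=1000)


class TestFilterAlongMode:
    def test_pure_one_mode_trajectory_reproduced(self, rng):
        from vibronet.synthetic import _rigid_mode_basis

        base = rng.normal(size=(4, 3)) * 5
        # displacement orthogonal to the rigid-body subspace so that the
        # superposition fit leaves the single mode intact
        direction = rng.normal(size=12)
        R = _rigid_mode_basis(base)
        direction -= R @ (R.T @ direction)
        direction /= np.linalg.norm(direction)
        amps = np.sin(np.linspace(0, 6, 30))
        coords = base[None] + (amps[:, None] * direction[None]).reshape(30, 4, 3)
        traj = Trajectory.from_arrays(coords=coords, dt=1.0)
        model = md.pca(traj, reference=base)
        filtered = md.filter_along_mode(traj, model, 0)
        np.testing.assert_allclose(filtered.coords, coords, atol=1e-6)

    def test_filtered_variance_equals_eigenvalue(self, fragment_switch_run):
        traj, _ = fragment_switch_run
        model = md.pca(traj)
        filtered = md.filter_along_mode(traj, model, 0)
        flat = filtered.coords.reshape(filtered.n_frames, -1)
        var = ((flat - flat.mean(0)) ** 2).sum(axis=1).mean()
        assert var == pytest.approx(model.eigenvalues[0], rel=1e-6)

    def test_zero_mode_gives_static_mean(self, rng):
        data = rng.normal(size=(20, 9))
        model = md.pca_matrix(data)
        # last mode of a rank-deficient series
        coords = np.repeat(data[:1], 20, axis=0) .reshape(20, 3, 3)
        traj = Trajectory.from_arrays(coords=coords + 0.0, dt=1.0)
        m2 = md.pca_matrix(coords.reshape(20, -1) + np.linspace(0, 1, 20)[:, None] * 0)
        assert m2.eigenvalues[0] == pytest.approx(0.0, abs=1e-20)


class TestCosineContent:
    def _model_with_projection(self, p):
        p = np.asarray(p, dtype=float)
        return md.PCModel(
            mean=np.zeros(3),
            eigenvalues=np.array([p.var()]),
            eigenvectors=np.eye(3)[:, :1],
            projections=p[:, None],
        )

    def test_half_cosine_scores_one(self):
        n = 1000
        p = np.cos(np.pi * (np.arange(n) + 0.5) / n)
        model = self._model_with_projection(p)
        assert md.cosine_content(model, 0) == pytest.approx(1.0, abs=1e-3)

    def test_fast_oscillation_scores_low(self):
        n = 1000
        p = np.cos(2 * np.pi * 25 * (np.arange(n) + 0.5) / n)
        model = self._model_with_projection(p)
        assert md.cosine_content(model, 0) < 0.01

    def test_constant_projection_rejected(self):
        model = self._model_with_projection(np.zeros(100))
        with pytest.raises(ValueError):
            md.cosine_content(model, 0)


class TestGNM:
    def test_straight_chain_sign_change_at_midpoint(self):
        n = 21
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) * 3.8
        hinges = md.gnm_hinges(coords, cutoff=8.0, n_modes=1)
        mid = (n - 1) / 2
        assert any(abs(h - mid) <= 1.0 for h in hinges[0])

    def test_kirchhoff_rows_sum_to_zero_and_single_zero_mode(self):
        traj, _ = syn.generate_two_domain_elastic(10, 2, seed=1)
        model = md.gnm(traj.coords[0], cutoff=10.0)
        np.testing.assert_allclose(model.kirchhoff.sum(axis=1), 0.0, atol=1e-10)
        assert (model.eigenvalues < 1e-8).sum() == 1

    def test_two_domain_hinge_matches_planted_linker(self):
        traj, truth = syn.generate_two_domain_elastic(20, 3, seed=0)
        hinges = md.gnm_hinges(traj, cutoff=10.0, n_modes=1)
        assert hinges[0], "no crossover found"
        dist = min(
            abs(h - l) for h in hinges[0] for l in truth.hinge_residues
        )
        assert dist <= 1

    def test_disconnected_graph_names_components(self):
        coords = np.zeros((6, 3))
        coords[3:, 0] = 100.0
        coords[:3, 1] = np.arange(3)
        coords[3:, 1] = np.arange(3)
        with pytest.raises(ValueError, match="disconnected"):
            md.gnm(coords, cutoff=5.0)

    def test_complete_contact_graph_degenerate_warns(self):
        coords = np.array(
            [[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3], [3, 3, 3.0]]
        )
        with pytest.warns(UserWarning, match="degenerate"):
            md.gnm_hinges(coords, cutoff=50.0, n_modes=1)
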