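"""Covariance analysis, projections, cosine content and PC screening."""

import numpy as np
import pytest

from _oracles import brute_force_covariance
from confdyn.essential_dynamics import (
    build_covariance,
    cosine_content,
    porcupine_vectors,
    project,
    select_pcs,
    variance_fraction,
)
from confdyn.synthetic_data import (
    GaussianTrajectorySpec,
    ca_topology,
    drifting_mode_series,
    generate_gaussian_trajectory,
    helix_structure,
)
from confdyn.trajectory_core import Trajectory


def traj_from_coords(coords):
    coords = np.asarray(coords, float)
    return Trajectory(
        ca_topology(coords.shape[1]), coords, np.arange(coords.shape[0], dtype=float)
    )


class TestCovariance:
    def test_single_atom_two_positions(self):
        coords = np.array([[[1.0, 0, 0]], [[-1.0, 0, 0]]])
        model = build_covariance(traj_from_coords(coords), selection="all", fit=False)
        expected = np.zeros((3, 3))
        expected[0, 0] = 1.0
        assert np.allclose(model.covariance, expected, atol=1e-12)

    def test_matches_brute_force_double_loop(self, rng):
        coords = rng.normal(size=(10, 5, 3))
        model = build_covariance(traj_from_coords(coords), selection="all", fit=False)
        oracle = brute_force_covariance(coords)
        assert np.max(np.abs(model.covariance - oracle)) < 1e-10

    def test_planted_covariance_recovered(self):
        spec = GaussianTrajectorySpec(
            n_residues=6, blocks=[(1, 3)], rho=0.8, n_frames=50_000, seed=11
        )
        traj = generate_gaussian_trajectory(spec)
        model = build_covariance(traj, selection="all", fit=False)
        target = spec.covariance()
        err = np.max(np.abs(model.covariance - target))
        assert err < 0.05 * np.max(target)

    def test_psd_and_orthonormal_invariants(self, small_gaussian_traj):
        traj, _ = small_gaussian_traj
        model = build_covariance(traj)
        lam = model.eigenvalues
        assert lam[0] >= lam[-1]
        assert lam.min() >= -1e-8 * lam.max()
        V = model.eigenvectors
        assert np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)
        assert np.isclose(lam.sum(), np.trace(model.covariance), rtol=1e-6)
        recon = V @ np.diag(lam) @ V.T
        assert np.max(np.abs(model.covariance - recon)) < 1e-8 * np.max(
            np.abs(model.covariance)
        )

    def test_requires_two_frames(self):
        coords = np.zeros((1, 4, 3))
        with pytest.raises(ValueError, match="2 frames"):
            build_covariance(traj_from_coords(coords))


class TestVarianceFraction:
    def test_fraction_properties(self, small_gaussian_traj):
        traj, _ = small_gaussian_traj
        model = build_covariance(traj)
        fracs = [variance_fraction(model, k) for k in range(1, model.n_modes + 1)]
        assert all(0 <= f <= 1 for f in fracs)
        assert np.all(np.diff(fracs) >= -1e-12)
        assert fracs[-1] == pytest.approx(1.0)

    def test_analytic_planted_spectrum(self):
        # three uncorrelated 1-D directions with variances 8, 1, 1
        rng = np.random.default_rng(5)
        F = 60_000
        coords = np.zeros((F, 3, 3))
        base = helix_structure(3) * 5.0
        amp = rng.normal(size=(F, 3)) * np.sqrt([8.0, 1.0, 1.0])
        for k in range(3):
            coords[:, k, 0] = amp[:, k]
        coords += base[None]
        model = build_covariance(traj_from_coords(coords), selection="all", fit=False)
        assert variance_fraction(model, 2) == pytest.approx(0.9, abs=0.01)

    def test_rank_one_covariance(self):
        coords = np.zeros((100, 2, 3))
        coords[:, 0, 0] = np.linspace(-1, 1, 100)
        model = build_covariance(traj_from_coords(coords), selection="all", fit=False)
        assert variance_fraction(model, 1) == pytest.approx(1.0)


class TestProjection:
    def test_variance_equals_eigenvalue(self, small_gaussian_traj):
        traj, _ = small_gaussian_traj
        model = build_covariance(traj)
        for k in (1, 2, 3):
            proj = project(traj, model, k)
            assert proj.variance == pytest.approx(
                model.eigenvalues[k - 1], rel=1e-8
            )
            assert abs(proj.values.mean()) < 1e-6

    def test_total_projection_variance_equals_trace(self, small_gaussian_traj):
        traj, _ = small_gaussian_traj
        model = build_covariance(traj)
        total = sum(
            project(traj, model, k).variance for k in range(1, model.n_modes + 1)
        )
        assert total == pytest.approx(np.trace(model.covariance), rel=1e-6)

    def test_static_trajectory_projects_to_zero(self, static_traj):
        model = build_covariance(static_traj)
        proj = project(static_traj, model, 1)
        assert np.allclose(proj.values, 0.0, atol=1e-8)

    def test_planted_dominant_mode_recovered(self):
        """A single dominant planted direction is found by PC1."""
        rng = np.random.default_rng(21)
        n_res, F = 8, 20_000
        base = helix_structure(n_res) * 4.0
        direction = rng.normal(size=3 * n_res)
        direction /= np.linalg.norm(direction)
        amp = rng.normal(0, 3.0, size=F)
        noise = rng.normal(0, 0.1, size=(F, 3 * n_res))
        coords = (base.reshape(-1)[None] + amp[:, None] * direction[None] + noise)
        traj = traj_from_coords(coords.reshape(F, n_res, 3))
        model = build_covariance(traj, selection="all", fit=False)
        overlap = abs(model.mode(1) @ direction)
        assert overlap >= 0.99


class TestCosineContent:
    def test_pure_half_cosine_is_one(self):
        p = drifting_mode_series(1.0, 1.0, 0.0, 1000, seed=0)
        assert cosine_content(p) == pytest.approx(1.0, abs=1e-3)

    def test_orthogonal_full_cosine_near_zero(self):
        """cos(2*pi*t) is orthogonal to the half-period cosine (quadrature)."""
        n = 2000
        t = (np.arange(n) + 0.5) / n
        p = np.cos(2 * np.pi * t)
        # quadrature oracle for the overlap integral
        overlap = (2.0 / n) * (p @ np.cos(np.pi * t)) ** 2 / (p @ p)
        assert overlap < 0.05
        assert cosine_content(p) == pytest.approx(overlap, abs=1e-12)

    def test_gaussian_noise_usually_below_threshold(self):
        hits = 0
        for seed in range(100):
            p = np.random.default_rng(seed).standard_normal(10_000)
            if cosine_content(p) < 0.1:
                hits += 1
        assert hits >= 95

    def test_all_zero_flagged(self):
        with pytest.raises(ValueError, match="all-zero"):
            cosine_content(np.zeros(100))


class TestSelectPcs:
    def make_model(self, traj):
        return build_covariance(traj)

    def test_passing_and_failing_combinations(self):
        clean1 = drifting_mode_series(0.0, 1.0, 1.0, 4000, seed=1)
        clean2 = drifting_mode_series(0.0, 1.0, 1.0, 4000, seed=2)
        drifty = drifting_mode_series(5.0, 1.0, 0.1, 4000, seed=3)
        assert cosine_content(drifty) > 0.1
        # both PCs converged
        assert select_pcs(None, [clean1, clean2]) == [1, 2]
        # only the first converged
        assert select_pcs(None, [clean1, drifty]) == [1]
        # none converged -> actionable error
        with pytest.raises(ValueError, match="extend the trajectory"):
            select_pcs(None, [drifty, drifty])


class TestPorcupine:
    def test_norms_sum_to_scale_and_cap(self, small_gaussian_traj):
        traj, _ = small_gaussian_traj
        model = build_covariance(traj)
        v = porcupine_vectors(model, 1, scale=10.0, cap=1e9)
        assert np.linalg.norm(v, axis=1).sum() == pytest.approx(10.0)
        capped = porcupine_vectors(model, 1, scale=1000.0, cap=15.0)
        assert np.linalg.norm(capped, axis=1).max() <= 15.0 + 1e-9

    def test_invalid_component_rejected(self, small_gaussian_traj):
        traj, _ = small_gaussian_traj
        model = build_covariance(traj)
        with pytest.raises(ValueError):
            porcupine_vectors(model, 0)
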