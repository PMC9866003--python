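"""PMF solver: Q objective, fitting, rotation, mass scaling."""

import numpy as np
import pytest

from pmfsa.pmf import (
    PMFConfig,
    apply_fpeak,
    default_fpeak_grid,
    fit,
    fpeak_scan,
    normalize_factors,
    q_value,
)


def brute_force_q(X, U, G, F):
    n, m = X.shape
    p = G.shape[1]
    total = 0.0
    for i in range(n):
        for j in range(m):
            e = X[i, j] - sum(G[i, k] * F[k, j] for k in range(p))
            total += (e / U[i, j]) ** 2
    return total


def block_truth(n=60, m=20, p=3, seed=0, noise=0.0):
    """Well-separated nonnegative truth: block-diagonal-ish profiles."""
    rng = np.random.default_rng(seed)
    # disjoint support per factor -> the factorization is identifiable
    F0 = np.zeros((p, m))
    for k in range(p):
        block = slice(k * (m // p), (k + 1) * (m // p))
        F0[k, block] = rng.uniform(1.0, 3.0, m // p)
    G0 = rng.lognormal(0.0, 0.5, size=(n, p))
    G0[rng.random((n, p)) < 0.3] = 0.0  # source-absent days pin rotations
    X = G0 @ F0
    if noise:
        X = np.maximum(0.0, X + rng.normal(0.0, noise, X.shape))
    return X, G0, F0


class TestQValue:
    def test_exact_factorization_gives_zero(self):
        rng = np.random.default_rng(1)
        G = rng.uniform(0, 1, (5, 2))
        F = rng.uniform(0, 1, (2, 4))
        X = G @ F
        assert q_value(X, np.ones_like(X), G, F) == 0.0

    def test_one_by_one_case(self):
        assert q_value([[3.0]], [[1.0]], [[1.0]], [[1.0]]) == pytest.approx(4.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 5, (6, 5))
        U = rng.uniform(0.1, 1.0, (6, 5))
        G = rng.uniform(0, 2, (6, 3))
        F = rng.uniform(0, 2, (3, 5))
        assert q_value(X, U, G, F) == pytest.approx(brute_force_q(X, U, G, F))

    def test_robust_huber_tail(self):
        # |r| = 2 > alpha = 1.5 -> contribution alpha*(2|r| - alpha) = 3.75
        q = q_value([[3.0]], [[1.0]], [[1.0]], [[1.0]],
                    robust=True, alpha=1.5)
        assert q == pytest.approx(1.5 * (2 * 2.0 - 1.5))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            q_value([[1.0]], [[0.0]], [[1.0]], [[1.0]])


class TestFit:
    def test_noiseless_recovery(self):
        X, G0, F0 = block_truth()
        U = np.ones_like(X)
        sol = fit(X, U, PMFConfig(n_factors=3, n_starts=3, seed=0))
        assert sol.Q_true / X.size < 1e-6
        # profiles match after optimal assignment
        from pmfsa.synthetic import match_factors
        res = match_factors(sol.F, F0)
        assert np.all(res.cosines > 0.99)

    def test_rank_one_matches_svd_oracle(self):
        # constant U: weighted rank-1 fit = leading SVD term (Perron
        # guarantees nonnegative singular vectors for a positive matrix)
        rng = np.random.default_rng(3)
        X = np.outer(rng.uniform(1, 2, 5), rng.uniform(1, 2, 4))
        X += rng.uniform(0, 0.05, X.shape)
        u_, s_, vt_ = np.linalg.svd(X)
        oracle = s_[0] * np.outer(np.abs(u_[:, 0]), np.abs(vt_[0]))
        sol = fit(X, np.ones_like(X), PMFConfig(n_factors=1, n_starts=2,
                                                seed=1))
        np.testing.assert_allclose(sol.reconstruct(), oracle, rtol=1e-4)

    def test_identical_seed_bitwise_identical(self):
        X, _, _ = block_truth(noise=0.1)
        U = np.full_like(X, 0.2)
        cfg = PMFConfig(n_factors=3, n_starts=3, seed=7)
        a = fit(X, U, cfg)
        b = fit(X, U, cfg)
        np.testing.assert_array_equal(a.q_trajectory, b.q_trajectory)
        np.testing.assert_array_equal(a.G, b.G)
        np.testing.assert_array_equal(a.F, b.F)

    def test_q_trajectory_monotone_nonincreasing(self):
        X, _, _ = block_truth(noise=0.2, seed=5)
        U = np.full_like(X, 0.2)
        sol = fit(X, U, PMFConfig(n_factors=3, n_starts=2, seed=2))
        traj = sol.q_trajectory
        assert np.all(np.diff(traj) <= 1e-9 * traj[:-1])

    def test_nonnegativity_everywhere(self):
        X, _, _ = block_truth(noise=0.3, seed=6)
        U = np.full_like(X, 0.3)
        sol = fit(X, U, PMFConfig(n_factors=4, n_starts=2, seed=3))
        assert np.all(sol.G >= 0) and np.all(sol.F >= 0)

    def test_too_many_factors_rejected(self):
        X = np.ones((4, 3))
        with pytest.raises(ValueError, match="exceeds"):
            fit(X, np.ones_like(X), PMFConfig(n_factors=5, n_starts=1))

    def test_non_finite_input_rejected(self):
        X = np.ones((4, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit(X, np.ones_like(X), PMFConfig(n_factors=2, n_starts=1))

    def test_more_factors_never_fit_worse_statistically(self):
        wins = 0
        for seed in range(10):
            X, _, _ = block_truth(n=30, m=12, p=3, seed=seed, noise=0.3)
            U = np.full_like(X, 0.3)
            q3 = fit(X, U, PMFConfig(n_factors=3, n_starts=3, seed=seed)).Q_true
            q4 = fit(X, U, PMFConfig(n_factors=4, n_starts=3, seed=seed)).Q_true
            wins += q4 <= q3
        assert wins >= 9

    def test_q_true_recomputable_from_stored_factors(self):
        X, _, _ = block_truth(noise=0.2, seed=9)
        U = np.full_like(X, 0.25)
        sol = fit(X, U, PMFConfig(n_factors=3, n_starts=2, seed=4))
        assert sol.Q_true == pytest.approx(q_value(X, U, sol.G, sol.F))


@pytest.fixture(scope="module")
def converged_fit():
    X, G0, F0 = block_truth(noise=0.2, seed=11)
    U = np.full_like(X, 0.25)
    sol = fit(X, U, PMFConfig(n_factors=3, n_starts=3, seed=11),
              species_names=[f"S{j}" for j in range(X.shape[1])])
    return X, U, sol


class TestFpeak:
    def test_phi_zero_is_identity(self, converged_fit):
        X, U, sol = converged_fit
        rot = apply_fpeak(sol, 0.0, X, U)
        np.testing.assert_array_equal(rot.G, sol.G)
        np.testing.assert_array_equal(rot.F, sol.F)
        assert rot.dq_from_base == 0.0

    def test_rotations_keep_nonnegativity_and_bounded_dq(self, converged_fit):
        X, U, sol = converged_fit
        for phi in (-0.5, -0.1, 0.1, 0.5):
            rot = apply_fpeak(sol, phi, X, U, dq_budget=0.2)
            assert np.all(rot.G >= 0) and np.all(rot.F >= 0)
            assert rot.Q_true >= sol.Q_true - 1e-6 * sol.Q_true
            within = rot.Q_true - sol.Q_true <= 0.2 * sol.Q_true
            assert within or rot.warnings  # budget overruns must warn

    def test_default_scan_has_21_rows_with_nonnegative_dq(self, converged_fit):
        X, U, sol = converged_fit
        rows = fpeak_scan(sol, X, U)
        assert len(rows) == 21
        assert len(default_fpeak_grid()) == 21
        phis = [r["phi"] for r in rows]
        assert phis == sorted(phis)
        assert all(r["dq"] >= 0 for r in rows)
        zero = next(r for r in rows if r["phi"] == 0.0)
        assert zero["dq"] == 0.0

    def test_out_of_range_phi_rejected(self, converged_fit):
        X, U, sol = converged_fit
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            apply_fpeak(sol, 1.5, X, U)


class TestNormalizeFactors:
    def test_scaled_contributions_sum_to_reconstructed_mass(self):
        rng = np.random.default_rng(13)
        n, m, p = 20, 6, 3
        G0 = rng.uniform(0.5, 2.0, (n, p))
        F0 = rng.uniform(0.1, 1.0, (p, m))
        F0[:, 0] = F0[:, 1:].sum(axis=1)  # mass column closes
        X = G0 @ F0
        U = np.full_like(X, 0.1)
        species = ["PM2.5"] + [f"S{j}" for j in range(1, m)]
        sol = fit(X, U, PMFConfig(n_factors=3, n_starts=3, seed=5),
                  species_names=species)
        scaled = normalize_factors(sol, "PM2.5")
        recon_mass = scaled.reconstruct()[:, 0]
        np.testing.assert_allclose(scaled.G.sum(axis=1), recon_mass,
                                   rtol=1e-6)

    def test_product_is_invariant_and_order_is_by_mean_contribution(self):
        rng = np.random.default_rng(14)
        G = rng.uniform(0.1, 1.0, (10, 3))
        F = rng.uniform(0.1, 1.0, (3, 4))
        from pmfsa.pmf import PMFSolution
        sol = PMFSolution(G=G, F=F, Q_true=0.0, Q_robust=0.0,
                          q_trajectory=np.empty(0), converged=True,
                          start_index=0,
                          species_names=["PM2.5", "a", "b", "c"])
        scaled = normalize_factors(sol, "PM2.5")
        np.testing.assert_allclose(scaled.reconstruct(), G @ F, rtol=1e-12)
        means = scaled.G.mean(axis=0)
        assert np.all(np.diff(means) <= 1e-12)

    def test_zero_mass_factor_flagged_not_divided(self):
        G = np.ones((5, 2))
        F = np.asarray([[2.0, 1.0, 1.0], [0.0, 1.0, 1.0]])
        from pmfsa.pmf import PMFSolution
        sol = PMFSolution(G=G, F=F, Q_true=0.0, Q_robust=0.0,
                          q_trajectory=np.empty(0), converged=True,
                          start_index=0, species_names=["PM2.5", "a", "b"])
        scaled = normalize_factors(sol, "PM2.5")
        assert len(scaled.flagged_factors) == 1
        assert np.all(np.isfinite(scaled.F))

    def test_missing_mass_species_errors(self):
        from pmfsa.pmf import PMFSolution
        sol = PMFSolution(G=np.ones((3, 1)), F=np.ones((1, 2)),
                          Q_true=0.0, Q_robust=0.0,
                          q_trajectory=np.empty(0), converged=True,
                          start_index=0, species_names=["a", "b"])
        with pytest.raises(ValueError, match="absent"):
            normalize_factors(sol, "PM2.5")
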