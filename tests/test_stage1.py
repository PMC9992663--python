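"""Unit and oracle tests for the four Stage-I weight estimators."""

import numpy as np
import pytest
from scipy import stats

from otters.lassosum import (
    LassosumConfig,
    fit_lassosum,
    fit_lassosum_single,
    objective,
    pseudovalidate,
    pseudovalidation_score,
)
from otters.ldpanel import LDStructure, partition_blocks
from otters.prscs import PRSCSConfig, fit_prscs, sample_gig_half
from otters.pt import PTConfig, fit_pt
from otters.sdpr import SDPRConfig, fit_sdpr

from conftest import random_correlation


def identity_ld(m):
    return LDStructure(R=np.eye(m), blocks=[(j, j + 1) for j in range(m)])


# ---------------------------------------------------------------------------
# P+T
# ---------------------------------------------------------------------------

class TestPT:
    def test_threshold_semantics(self):
        ld = identity_ld(2)
        betas, p = np.array([0.3, 0.2]), np.array([1e-5, 0.3])
        w = fit_pt(betas, p, ld, PTConfig(p_threshold=0.001))
        np.testing.assert_allclose(w, [0.3, 0.0])

    def test_clump_removes_correlated_snp(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        ld = LDStructure(R=R)
        w = fit_pt(np.array([0.3, 0.25]), np.array([1e-5, 1e-4]), ld,
                   PTConfig(p_threshold=0.05))
        np.testing.assert_allclose(w, [0.3, 0.0])

    @pytest.mark.parametrize("p_val,in001,in05", [(0.01, False, True), (0.0005, True, True)])
    def test_boundary_inclusive(self, p_val, in001, in05):
        ld = identity_ld(1)
        for thr, expect in ((0.001, in001), (0.05, in05)):
            w = fit_pt(np.array([0.1]), np.array([p_val]), ld, PTConfig(p_threshold=thr))
            assert bool(w[0] != 0) is expect

    def test_threshold_nesting_property(self, rng):
        m = 30
        R = random_correlation(m, rng)
        ld = LDStructure(R=R)
        betas, p = rng.normal(size=m), rng.random(m) ** 2
        w_small = fit_pt(betas, p, ld, PTConfig(p_threshold=0.01))
        w_large = fit_pt(betas, p, ld, PTConfig(p_threshold=0.2))
        small_set = set(np.flatnonzero(w_small))
        large_set = set(np.flatnonzero(w_large))
        assert small_set <= large_set
        # nonzero weights equal the marginal betas exactly
        np.testing.assert_array_equal(w_large[list(large_set)], betas[list(large_set)])


# ---------------------------------------------------------------------------
# lassosum
# ---------------------------------------------------------------------------

class TestLassosum:
    def test_identity_ld_no_penalty_returns_betas(self):
        betas = np.array([0.3, -0.1, 0.05])
        w, ok = fit_lassosum_single(betas, identity_ld(3), s=0.5, lam=0.0)
        assert ok
        np.testing.assert_allclose(w, betas, atol=1e-10)

    def test_identity_ld_soft_threshold_closed_form(self):
        w, _ = fit_lassosum_single(np.array([0.3, 0.05]), identity_ld(2), s=0.5, lam=0.1)
        np.testing.assert_allclose(w, [0.2, 0.0], atol=1e-10)

    @staticmethod
    def _ista(betas, R, s, lam, iters=200_000):
        """Independent proximal-gradient (ISTA) solver of the same objective."""
        m = len(betas)
        H = (1 - s) * R + s * np.eye(m)  # smooth part: w'Hw - 2 betas'w
        step = 1.0 / (2 * np.linalg.eigvalsh(H).max())
        w = np.zeros(m)
        for _ in range(iters):
            grad = 2 * (H @ w - betas)
            x = w - step * grad
            w = np.sign(x) * np.maximum(np.abs(x) - 2 * lam * step, 0.0)
        return w

    def test_matches_proximal_gradient_oracle(self, rng):
        """Coordinate descent equals an independent solver on the explicit objective."""
        for m in (2, 5, 10):
            R = random_correlation(m, rng)
            ld = LDStructure(R=R, blocks=[(0, m)])
            betas = rng.normal(scale=0.2, size=m)
            s, lam = 0.5, 0.05
            w_cd, _ = fit_lassosum_single(betas, ld, s, lam, max_iter=5000, tol=1e-14)
            w_pg = self._ista(betas, R, s, lam)
            assert abs(objective(w_cd, betas, R, s, lam)
                       - objective(w_pg, betas, R, s, lam)) < 1e-10
            np.testing.assert_allclose(w_cd, w_pg, atol=1e-6)

    def test_two_snp_example_against_oracle(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        ld = LDStructure(R=R)
        betas = np.array([0.3, 0.2])
        w_cd, _ = fit_lassosum_single(betas, ld, s=0.5, lam=0.05, max_iter=5000, tol=1e-14)
        np.testing.assert_allclose(w_cd, self._ista(betas, R, 0.5, 0.05), atol=1e-6)

    def test_objective_nonincreasing_across_sweeps(self, rng):
        m = 8
        R = random_correlation(m, rng)
        ld = LDStructure(R=R, blocks=[(0, m)])
        betas = rng.normal(scale=0.2, size=m)
        vals = []
        for n_sweeps in range(1, 8):
            w, _ = fit_lassosum_single(betas, ld, 0.2, 0.01, max_iter=n_sweeps, tol=0.0)
            vals.append(objective(w, betas, R, 0.2, 0.01))
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_l1_norm_nonincreasing_in_lambda(self, rng):
        m = 6
        R = random_correlation(m, rng)
        ld = LDStructure(R=R, blocks=[(0, m)])
        betas = rng.normal(scale=0.3, size=m)
        norms = [np.abs(fit_lassosum_single(betas, ld, 0.5, lam, 2000, 1e-10)[0]).sum()
                 for lam in np.logspace(-3, -0.5, 8)]
        assert all(b <= a + 1e-8 for a, b in zip(norms, norms[1:]))

    def test_s_equal_one_is_elementwise_soft_threshold(self, rng):
        betas = rng.normal(size=5)
        ld = LDStructure(R=random_correlation(5, rng))
        w, _ = fit_lassosum_single(betas, ld, s=1.0, lam=0.1)
        expected = np.sign(betas) * np.maximum(np.abs(betas) - 0.1, 0.0)
        np.testing.assert_allclose(w, expected)

    def test_pseudovalidation_single_candidate(self):
        betas = np.array([0.3, 0.1])
        ld = identity_ld(2)
        key, w, _ = pseudovalidate({(0.5, 0.01): betas.copy()}, betas, ld)
        assert key == (0.5, 0.01)
        np.testing.assert_array_equal(w, betas)

    def test_pseudovalidation_norm_identity(self):
        betas = np.array([0.3, -0.4])
        assert pseudovalidation_score(betas, betas, identity_ld(2)) == pytest.approx(
            np.linalg.norm(betas)
        )

    def test_pseudovalidation_matches_exhaustive_scoring(self, rng):
        betas = np.array([0.25, 0.1])
        ld = LDStructure(R=np.array([[1.0, 0.3], [0.3, 1.0]]))
        cands = {(0.2, 0.01): np.array([0.2, 0.05]),
                 (0.5, 0.02): np.array([0.25, 0.0]),
                 (0.9, 0.05): np.array([0.1, 0.1])}
        key, _, best = pseudovalidate(cands, betas, ld)
        scores = {k: pseudovalidation_score(v, betas, ld) for k, v in cands.items()}
        assert key == max(scores, key=scores.get)
        assert best == pytest.approx(max(scores.values()))

    def test_all_zero_candidates_give_empty_weights(self):
        betas = np.array([0.01, 0.02])
        cfg = LassosumConfig(s_grid=[1.0], lambda_grid=[0.5])
        w, chosen = fit_lassosum(betas, identity_ld(2), cfg)
        assert chosen is None and not np.any(w)


# ---------------------------------------------------------------------------
# SDPR
# ---------------------------------------------------------------------------

class TestSDPR:
    def test_null_input_posterior_near_zero(self):
        m = 10
        cfg = SDPRConfig(iters=600, burnin=200, seed=1)
        w, draws = fit_sdpr(np.zeros(m), 500, identity_ld(m), cfg)
        se = draws.w_draws.std(axis=0) / np.sqrt(draws.w_draws.shape[0]) + 1e-12
        assert np.all(np.abs(w) <= 3 * se + 1e-4)

    def test_single_snp_conjugate_oracle(self):
        """Fixed active component: posterior mean is the normal-normal shrinkage."""
        n, btilde = 400, 0.2
        s2_rel = 20.0          # relative scale; natural prior variance below
        v = s2_rel * 1.0 / n   # sigma2_eps fixed at 1
        cfg = SDPRConfig(iters=4200, burnin=200, seed=7,
                         fix_sigma2_k=(s2_rel,), fix_assign_active=True,
                         fix_sigma2_eps=1.0)
        w, draws = fit_sdpr(np.array([btilde]), n, identity_ld(1), cfg)
        expected = n * btilde * v / (n * v + 1.0)
        mc_se = draws.w_draws.std() / np.sqrt(draws.w_draws.shape[0])
        assert abs(w[0] - expected) <= 3 * mc_se

    def test_seeded_determinism(self, small_ld):
        betas = np.linspace(-0.2, 0.2, small_ld.m)
        cfg = SDPRConfig(iters=150, burnin=50, seed=11)
        w1, _ = fit_sdpr(betas, 300, small_ld, cfg)
        w2, _ = fit_sdpr(betas, 300, small_ld, cfg)
        np.testing.assert_array_equal(w1, w2)

    def test_shrinkage_toward_zero_on_identity_ld(self, rng):
        m = 12
        betas = rng.normal(scale=0.1, size=m)
        cfg = SDPRConfig(iters=800, burnin=200, seed=3)
        w, draws = fit_sdpr(betas, 500, identity_ld(m), cfg)
        se = draws.w_draws.std(axis=0) / np.sqrt(draws.w_draws.shape[0])
        # on independent SNPs the GLS solution is btilde itself
        assert np.all(np.abs(w) <= np.abs(betas) + 3 * se + 1e-6)

    def test_mixture_proportions_sum_to_one(self, small_ld):
        betas = np.zeros(small_ld.m)
        _, draws = fit_sdpr(betas, 300, small_ld, SDPRConfig(iters=120, burnin=20, seed=5))
        np.testing.assert_allclose(draws.pi_draws.sum(axis=1), 1.0, atol=1e-12)

    def test_strong_signal_parameter_recovery(self):
        n, m = 5000, 20
        rng = np.random.default_rng(17)
        true_w = np.zeros(m)
        true_w[7] = 0.3
        betas = true_w + rng.normal(scale=1 / np.sqrt(n), size=m)
        w, _ = fit_sdpr(betas, n, identity_ld(m), SDPRConfig(iters=800, burnin=200, seed=2))
        assert abs(w[7] - 0.3) < 0.05
        assert np.argmax(np.abs(w)) == 7


# ---------------------------------------------------------------------------
# PRS-CS
# ---------------------------------------------------------------------------

class TestPRSCS:
    def test_frozen_psi_matches_ridge_closed_form(self, rng):
        m = 8
        R = random_correlation(m, rng)
        blocks = partition_blocks(R)
        ld = LDStructure(R=R, blocks=blocks)
        betas = rng.normal(scale=0.15, size=m)
        psi = rng.uniform(0.05, 1.0, size=m)
        cfg = PRSCSConfig(iters=4200, burnin=200, seed=13, fix_psi=tuple(psi))
        w, state = fit_prscs(betas, 400, ld, cfg)
        ridge = np.zeros(m)
        for a, b in blocks:
            A = R[a:b, a:b] + np.diag(1.0 / psi[a:b])
            ridge[a:b] = np.linalg.solve(A, betas[a:b])
        # 5e-3 covers ~3 MC standard errors of a 4000-draw posterior mean
        np.testing.assert_allclose(w, ridge, atol=5e-3)
        assert np.all(state.sigma2_eps > 0)

    def test_null_input_posterior_near_zero(self):
        m = 10
        cfg = PRSCSConfig(phi=1e-4, iters=600, burnin=200, seed=4)
        w, _ = fit_prscs(np.zeros(m), 500, identity_ld(m), cfg)
        assert np.all(np.abs(w) < 3 * np.sqrt(1 / 500) / np.sqrt(400) + 5e-3)

    def test_seeded_determinism(self, small_ld):
        betas = np.linspace(-0.2, 0.2, small_ld.m)
        cfg = PRSCSConfig(iters=150, burnin=50, seed=21)
        w1, _ = fit_prscs(betas, 300, small_ld, cfg)
        w2, _ = fit_prscs(betas, 300, small_ld, cfg)
        np.testing.assert_array_equal(w1, w2)

    def test_shrinkage_state_invariants(self, small_ld):
        betas = np.full(small_ld.m, 0.05)
        _, state = fit_prscs(betas, 300, small_ld,
                             PRSCSConfig(iters=200, burnin=50, seed=6))
        assert np.all(state.psi > 0) and np.all(state.delta > 0)
        assert np.all(state.sigma2_eps > 0)

    def test_heavy_tail_spares_large_effects(self):
        """One strong eQTL among nulls: its weight dwarfs the null median."""
        n, m = 2000, 30
        rng = np.random.default_rng(23)
        betas = rng.normal(scale=1 / np.sqrt(n), size=m)
        betas[11] = 0.3
        cfg = PRSCSConfig(phi=1e-4, iters=800, burnin=200, seed=9)
        w, _ = fit_prscs(betas, n, identity_ld(m), cfg)
        null_med = np.median(np.abs(np.delete(w, 11)))
        assert abs(w[11]) >= 10 * null_med

    def test_global_shrinkage_monotonicity(self):
        """Smaller phi never inflates ||w||_1 on null input (paired seeds)."""
        m = 20
        betas = np.zeros(m)
        norms = {}
        for phi in (1e-2, 1e-4):
            tot = 0.0
            for seed in range(5):
                w, _ = fit_prscs(betas, 500, identity_ld(m),
                                 PRSCSConfig(phi=phi, iters=300, burnin=100, seed=seed))
                tot += np.abs(w).sum()
            norms[phi] = tot / 5
        assert norms[1e-4] <= norms[1e-2] + 1e-6

    def test_gig_half_order_moments_match_scipy(self, rng):
        """wald-identity sampler agrees with scipy.stats.geninvgauss moments."""
        a_par, b_par = 3.0, 2.0
        draws = sample_gig_half(np.full(20000, a_par), np.full(20000, b_par), rng)
        omega = np.sqrt(a_par * b_par)
        scale = np.sqrt(b_par / a_par)
        ref = stats.geninvgauss(0.5, omega, scale=scale)
        assert draws.mean() == pytest.approx(ref.mean(), rel=0.05)
        assert draws.var() == pytest.approx(ref.var(), rel=0.15)
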