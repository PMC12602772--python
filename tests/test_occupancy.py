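"""Occupancy likelihood, sampler, convergence diagnostics, GOF, prediction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit as slogit

from owlbaci import occupancy as occ
from owlbaci._util import expit
from owlbaci.synthetic import simulate_simple_history

# ---------------------------------------------------------------------------
# helpers


def brute_force_loglik(psi, p, y):
    """Enumerate the latent state z explicitly."""
    obs = ~np.isnan(np.asarray(y, float))
    yo = np.asarray(y, float)[obs]
    po = np.asarray(p, float)[obs]
    l_occ = psi * np.prod(np.where(yo == 1, po, 1 - po))
    l_empty = (1 - psi) * (0.0 if np.any(yo == 1) else 1.0)
    return float(np.log(l_occ + l_empty))


def intercept_only_design(y):
    n, T = y.shape
    return occ.OccupancyDesign(
        y=y, X_psi=np.ones((n, 1)), X_p=np.ones((n, T, 1)),
        year_idx=np.zeros(n, int), site_idx=np.arange(n),
        psi_cols=["(intercept)"], p_cols=["(intercept)"])


# ---------------------------------------------------------------------------


class TestBuildDesign:
    @pytest.mark.parametrize(
        "model,cols",
        [
            ("fire_tc", ["(intercept)", "burn", "allpostburn"]),
            ("bo_td", ["(intercept)", "site_type", "lethal1", "lethal2", "lethal3plus"]),
            ("int_tc", ["(intercept)", "site_type", "burn", "postlethal_x_burnyrs"]),
        ],
    )
    def test_equation_columns(self, model, cols, tiny_detections, tiny_survey):
        from owlbaci.encounters import build_history, invader_covariate

        det, info = tiny_detections
        hist = build_history(det, tiny_survey.deployments, tiny_survey.arus, "flammulated")
        inv = invader_covariate(build_history(det, tiny_survey.deployments,
                                              tiny_survey.arus, "barred_owl"))
        covs = info["covariates"].merge(inv, on=["hexagon", "season"], how="left"
                                        ).fillna({"invader": 0})
        d = occ.build_design(model, covs, hist)
        assert d.psi_cols == cols
        assert d.X_psi.shape[1] == len(cols)
        assert (d.X_psi[:, 0] == 1).all()

    def test_missing_covariate_names_the_column(self, tiny_detections, tiny_survey):
        from owlbaci.encounters import build_history

        det, info = tiny_detections
        hist = build_history(det, tiny_survey.deployments, tiny_survey.arus, "flammulated")
        covs = info["covariates"].drop(columns=["allpostburn"])
        with pytest.raises(ValueError, match="allpostburn"):
            occ.build_design("fire_tc", covs, hist)


class TestSiteLogLikelihood:
    def test_detected_history(self):
        # psi * p * (1-p) = 0.5 * 0.5 * 0.5
        got = occ.site_log_likelihood(0.5, [0.5, 0.5], [1, 0])
        assert got == pytest.approx(np.log(0.125))

    def test_all_zero_history_marginalizes_latent_state(self):
        # 0.5 * 0.25 + 0.5 = 0.625
        got = occ.site_log_likelihood(0.5, [0.5, 0.5], [0, 0])
        assert got == pytest.approx(np.log(0.625))

    def test_all_missing_is_uninformative(self):
        assert occ.site_log_likelihood(0.3, [0.5, 0.5], [np.nan, np.nan]) == 0.0

    def test_exhaustive_enumeration_oracle(self):
        """Every 2-4 period history (including missing periods) matches the
        brute-force sum over the latent occupancy state."""
        rng = np.random.default_rng(0)
        for T in (2, 3, 4):
            p = rng.uniform(0.1, 0.9, T)
            psi = rng.uniform(0.05, 0.95)
            for vals in itertools.product([0.0, 1.0, np.nan], repeat=T):
                y = np.array(vals)
                got = occ.site_log_likelihood(psi, p, y)
                assert got == pytest.approx(brute_force_loglik(psi, p, y), rel=1e-12)

    def test_nonfinite_detection_probability_rejected(self):
        with pytest.raises(ValueError):
            occ.site_log_likelihood(0.5, [np.nan], [0.0])


class TestGelmanRubin:
    def test_well_mixed_chains_near_one(self, rng):
        chains = rng.normal(0, 1, (4, 1000))
        assert occ.gelman_rubin(chains) <= 1.05

    def test_separated_chains_flagged(self, rng):
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert occ.gelman_rubin(chains) > 1.1

    def test_matches_textbook_formula(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 6.0]])
        m, n = x.shape
        W = x.var(axis=1, ddof=1).mean()
        B = n * x.mean(axis=1).var(ddof=1)
        want = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert occ.gelman_rubin(x) == pytest.approx(want, rel=1e-12)

    def test_single_chain_is_an_error(self):
        with pytest.raises(ValueError):
            occ.gelman_rubin(np.zeros((1, 100)))


class TestSampler:
    def test_same_seed_identical_draws(self):
        y, _ = simulate_simple_history(0.5, 0.5, 50, 4, seed=1)
        d = intercept_only_design(y)
        a = occ.sample_posterior(d, chains=2, iters=100, seed=5, random_effects=False)
        b = occ.sample_posterior(d, chains=2, iters=100, seed=5, random_effects=False)
        assert np.array_equal(a.beta, b.beta) and np.array_equal(a.alpha, b.alpha)

    def test_conjugate_oracle_with_perfect_detection(self):
        """With p pinned to 1 and a flat prior on logit(psi), the posterior of
        psi is Beta(k, n-k) exactly (every z is observed)."""
        y, z = simulate_simple_history(0.6, 1.0, 300, 5, seed=2)
        d = intercept_only_design(y)
        draws = occ.sample_posterior(d, priors=occ.Priors(flat=True), chains=2,
                                     iters=3000, seed=7, fixed_p=1.0,
                                     random_effects=False)
        psi = expit(draws.stacked("beta")[:, 0])
        k = int((y == 1).any(axis=1).sum())
        n = y.shape[0]
        from scipy.stats import beta as beta_dist

        want_mean = k / n
        want_sd = beta_dist(k, n - k).std()
        assert psi.mean() == pytest.approx(want_mean, abs=3 * want_sd / np.sqrt(50))
        assert psi.std() == pytest.approx(want_sd, rel=0.15)

    def test_recovers_constant_psi_and_p(self):
        y, _ = simulate_simple_history(0.6, 0.7, 500, 8, seed=3)
        d = intercept_only_design(y)
        draws = occ.sample_posterior(d, chains=2, iters=800, seed=9,
                                     random_effects=False)
        psi_hat = expit(draws.stacked("beta")[:, 0]).mean()
        p_hat = expit(draws.stacked("alpha")[:, 0]).mean()
        assert psi_hat == pytest.approx(0.6, abs=0.05)
        assert p_hat == pytest.approx(0.7, abs=0.05)

    def test_constant_column_rejected(self):
        y, _ = simulate_simple_history(0.5, 0.5, 20, 3, seed=4)
        d = intercept_only_design(y)
        d.X_psi = np.column_stack([d.X_psi, np.ones(20)])
        d.psi_cols = ["(intercept)", "const2"]
        with pytest.raises(ValueError, match="constant"):
            occ.sample_posterior(d, chains=2, iters=50)


class TestGOF:
    def test_statistic_matches_hand_computation(self):
        """Two-period toy: 3 fully observed rows with histories (1,0), (0,0),
        (0,0) at psi = p = 0.5. Expected counts: E(1,0) = 3/8, E(0,0) = 15/8;
        unpooled chi-square plus unobserved remainder = 0.625^2/0.375 +
        0.125^2/1.875 + 0.75."""
        y = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
        psi = np.full(3, 0.5)
        p = np.full((3, 2), 0.5)
        want = 0.625**2 / 0.375 + 0.125**2 / 1.875 + 0.75
        got = occ._history_stat(y, psi, p, pool_below=0.0)
        assert got == pytest.approx(want, rel=1e-12)

    def test_pooling_merges_sparse_histories(self):
        y = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
        psi = np.full(3, 0.5)
        p = np.full((3, 2), 0.5)
        # with pooling at E<2 all three cells merge: statistic collapses to 0
        assert occ._history_stat(y, psi, p, pool_below=2.0) == pytest.approx(0.0)

    def test_p_value_sane_under_generating_model(self):
        y, _ = simulate_simple_history(0.5, 0.4, 150, 6, seed=6)
        d = intercept_only_design(y)
        draws = occ.sample_posterior(d, chains=2, iters=400, seed=11,
                                     random_effects=False)
        g = occ.mb_gof(draws, d, n_rep=100, seed=12)
        assert 0.01 < g["p_value"] < 0.99

    def test_n_rep_validated(self):
        y, _ = simulate_simple_history(0.5, 0.4, 20, 3, seed=6)
        d = intercept_only_design(y)
        draws = occ.sample_posterior(d, chains=2, iters=50, seed=1,
                                     random_effects=False)
        with pytest.raises(ValueError):
            occ.mb_gof(draws, d, n_rep=0)


class TestPredict:
    def _draws(self, beta, sigmas=False):
        k = beta.shape[-1]
        return occ.PosteriorDraws(
            beta=beta.reshape(1, -1, k), alpha=None,
            u_year=None, u_site=None,
            sigma_year=np.full((1, beta.shape[0]), 0.3) if sigmas else None,
            sigma_site=np.full((1, beta.shape[0]), 0.3) if sigmas else None,
            psi_cols=["(intercept)"] + [f"x{i}" for i in range(k - 1)],
            p_cols=[], burn=0)

    def test_zero_coefficients_give_half(self):
        draws = self._draws(np.zeros((100, 2)))
        out = occ.predict_occupancy(draws, {"x0": 1.0}, marginalize="zero")
        assert out["mean"] == 0.5 and out["ci"] == (0.5, 0.5)

    def test_monotone_in_positive_covariate(self, rng):
        beta = np.abs(rng.normal(1, 0.2, (200, 2)))
        draws = self._draws(beta)
        lo = occ.predict_occupancy(draws, {"x0": 0.2}, marginalize="zero")
        hi = occ.predict_occupancy(draws, {"x0": 0.8}, marginalize="zero")
        assert hi["mean"] > lo["mean"]

    def test_missing_profile_field_is_an_error(self):
        draws = self._draws(np.zeros((10, 2)))
        with pytest.raises(ValueError, match="x0"):
            occ.predict_occupancy(draws, {})

    def test_marginalizing_random_effects_widens_interval(self, rng):
        beta = rng.normal(slogit(0.3), 0.05, (400, 1))
        d0 = self._draws(beta, sigmas=True)
        zero = occ.predict_occupancy(d0, {}, marginalize="zero")
        drawn = occ.predict_occupancy(d0, {}, marginalize="draw", seed=3)
        assert drawn["ci"][1] - drawn["ci"][0] > zero["ci"][1] - zero["ci"][0]


def test_likelihood_row_order_invariance(rng):
    """Total design log-likelihood is invariant to permuting rows."""
    y, _ = simulate_simple_history(0.4, 0.6, 40, 5, seed=8)
    psi = rng.uniform(0.2, 0.8, 40)
    p = rng.uniform(0.2, 0.8, (40, 5))
    total = sum(occ.site_log_likelihood(psi[i], p[i], y[i]) for i in range(40))
    perm = rng.permutation(40)
    total_p = sum(occ.site_log_likelihood(psi[i], p[i], y[i]) for i in perm)
    assert total == pytest.approx(total_p)
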