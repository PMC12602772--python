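"""Posterior overlap, occurrence model, marginal effects, standard ellipses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from owlbaci import contrast as ct
from owlbaci._util import expit
from owlbaci.occupancy import PosteriorDraws


class TestPosteriorOverlap:
    def test_identical_samples_near_one(self, rng):
        a = rng.normal(0, 1, 5000)
        assert ct.posterior_overlap(a, a).overlap >= 0.95

    def test_unit_shift_matches_analytic_normal_overlap(self, rng):
        a = rng.normal(0, 1, 5000)
        b = rng.normal(2, 1, 5000)
        want = 2 * stats.norm.cdf(-1)  # 0.3173
        assert ct.posterior_overlap(a, b).overlap == pytest.approx(want, abs=0.02)

    def test_disjoint_supports_near_zero(self, rng):
        a = rng.normal(0, 1, 2000)
        res = ct.posterior_overlap(a, a + 50)
        assert res.overlap < 0.001 and res.meaningful

    def test_symmetry_and_shift_invariance(self, rng):
        a = rng.normal(0, 1, 2000)
        b = rng.normal(1, 2, 2000)
        ab = ct.posterior_overlap(a, b).overlap
        ba = ct.posterior_overlap(b, a).overlap
        shifted = ct.posterior_overlap(a + 7, b + 7).overlap
        assert ab == pytest.approx(ba, abs=1e-12)
        assert ab == pytest.approx(shifted, abs=1e-6)

    def test_degenerate_draws_rejected(self):
        with pytest.raises(ValueError):
            ct.posterior_overlap(np.ones(100), np.random.normal(size=100))

    def test_fifteen_percent_rule(self, rng):
        near = ct.posterior_overlap(rng.normal(0, 1, 3000), rng.normal(0.1, 1, 3000))
        far = ct.posterior_overlap(rng.normal(0, 1, 3000), rng.normal(6, 1, 3000))
        assert not near.meaningful and far.meaningful


class TestRemovalContrasts:
    def _draws(self, n=2000, seed=0, shift=2.0):
        rng = np.random.default_rng(seed)
        beta = np.column_stack([
            rng.normal(-1.2, 0.2, n),        # intercept
            rng.normal(-1.1, 0.2, n),        # site_type
            rng.normal(shift, 0.2, n),       # allpostlethal
        ])
        return PosteriorDraws(beta.reshape(1, n, 3), None, None, None, None, None,
                              ["(intercept)", "site_type", "allpostlethal"], [], 0)

    def test_large_removal_effect_is_meaningful(self):
        res = ct.removal_contrasts(self._draws(shift=2.0), "bo_tc")
        assert set(res) == {"allpostlethal"}
        assert res["allpostlethal"].overlap < 0.15

    def test_null_effect_overlaps_heavily(self):
        res = ct.removal_contrasts(self._draws(shift=0.0), "bo_tc")
        assert res["allpostlethal"].overlap > 0.5

    def test_model_without_site_type_rejected(self):
        d = self._draws()
        d.psi_cols = ["(intercept)", "burn", "allpostburn"]
        with pytest.raises(ValueError):
            ct.removal_contrasts(d, "fire_tc")


class TestOccurrenceModel:
    def test_null_covariate_has_small_coefficient(self, rng):
        X = pd.DataFrame({"x": rng.normal(0, 1, 1000)})
        y = (rng.random(1000) < 0.4).astype(int)
        fit = ct.fit_occurrence_logistic(y, X)
        assert abs(fit.params["x"] / fit.bse["x"]) < 3

    def test_recovers_strong_seral_preference(self, rng):
        # generating coefficients mirror a strong forest-structure effect
        n = 1000
        X = pd.DataFrame({"seral": rng.uniform(0, 1, n)})
        eta = -1.0 + 4.2 * (X["seral"] - 0.5)
        y = (rng.random(n) < expit(eta)).astype(int)
        fit = ct.fit_occurrence_logistic(y, X)
        assert fit.ci.loc["seral", "lo"] <= 4.2 <= fit.ci.loc["seral", "hi"]

    def test_constant_outcome_is_an_error(self):
        X = pd.DataFrame({"x": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError):
            ct.fit_occurrence_logistic(np.zeros(3), X)

    def test_separation_falls_back_flagged(self):
        X = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)]})
        y = np.r_[np.zeros(20), np.ones(20)]
        fit = ct.fit_occurrence_logistic(y, X)
        assert fit.flagged and np.isfinite(fit.params).all()


class TestAME:
    def _fit(self, rng, beta1=1.0, n=500):
        X = pd.DataFrame({"x": rng.normal(0, 1, n)})
        y = (rng.random(n) < expit(0.5 + beta1 * X["x"])).astype(int)
        return ct.fit_occurrence_logistic(y, X)

    def test_zero_coefficient_zero_ame(self, rng):
        fit = self._fit(rng)
        fit.params["x"] = 0.0
        assert ct.average_marginal_effect(fit, "x") == 0.0

    def test_single_row_at_linear_predictor_zero(self):
        fit = ct.OccurrenceFit(
            params=pd.Series({"const": 0.0, "x": 1.0}),
            bse=pd.Series({"const": 1.0, "x": 1.0}), ci=pd.DataFrame(),
            X=pd.DataFrame({"const": [1.0], "x": [0.0]}), y=np.array([1.0]),
            flagged=False)
        assert ct.average_marginal_effect(fit, "x") == pytest.approx(0.25)

    def test_matches_finite_difference_oracle(self, rng):
        fit = self._fit(rng, beta1=0.8)
        eps = 1e-6
        p0 = expit(fit.X.to_numpy() @ fit.params.to_numpy())
        Xe = fit.X.copy()
        Xe["x"] += eps
        p1 = expit(Xe.to_numpy() @ fit.params.to_numpy())
        fd = float(np.mean((p1 - p0) / eps))
        assert ct.average_marginal_effect(fit, "x") == pytest.approx(fd, abs=1e-6)

    def test_unknown_covariate_is_an_error(self, rng):
        with pytest.raises(ValueError):
            ct.average_marginal_effect(self._fit(rng), "nope")


class TestStandardEllipse:
    def test_area_formula_on_exact_unit_covariance(self, rng):
        # whiten a sample so its sample covariance is exactly the identity
        pts = rng.normal(0, 1, (500, 2))
        pts = (pts - pts.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(pts.T))).T
        e = ct.standard_ellipse(pts, 0.85)
        want = np.pi * stats.chi2.ppf(0.85, 2)  # pi * 3.794 ~ 11.92
        assert e.area == pytest.approx(want, rel=1e-6)

    def test_axis_scaling_doubles_area(self, rng):
        pts = rng.normal(0, 1, (400, 2))
        e1 = ct.standard_ellipse(pts)
        pts2 = pts * np.array([2.0, 1.0])
        e2 = ct.standard_ellipse(pts2)
        assert e2.area == pytest.approx(2 * e1.area, rel=1e-9)

    def test_area_increasing_in_level(self, rng):
        pts = rng.normal(0, 1, (200, 2))
        areas = [ct.standard_ellipse(pts, lv).area for lv in (0.5, 0.85, 0.95)]
        assert areas == sorted(areas)

    def test_coverage_near_level(self, rng):
        pts = rng.multivariate_normal([0, 0], [[2, 0.7], [0.7, 1]], 20000)
        e = ct.standard_ellipse(pts, 0.85)
        assert e.contains(pts).mean() == pytest.approx(0.85, abs=0.02)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            ct.standard_ellipse(pts)


class TestEllipseOverlap:
    def _unit_circle(self, center, level=0.85):
        cov = np.eye(2) / stats.chi2.ppf(level, 2)
        return ct.EllipseSummary(np.asarray(center, float), cov, level)

    def test_identical_ellipses_full_overlap(self):
        e = self._unit_circle((0, 0))
        inter, frac = ct.ellipse_overlap(e, e)
        assert frac == pytest.approx(1.0, abs=1e-3)

    def test_disjoint_ellipses(self):
        inter, frac = ct.ellipse_overlap(self._unit_circle((0, 0)),
                                         self._unit_circle((10, 0)))
        assert inter == 0.0 and frac == 0.0

    def test_unit_circles_offset_one_match_lens_formula(self):
        inter, _ = ct.ellipse_overlap(self._unit_circle((0, 0)),
                                      self._unit_circle((1, 0)))
        lens = 2 * np.arccos(0.5) - 0.5 * np.sqrt(3)
        assert inter == pytest.approx(lens, rel=1e-3)

    def test_polygonal_approximation_converges(self):
        lens = 2 * np.arccos(0.5) - 0.5 * np.sqrt(3)
        errs = []
        for nv in (64, 256, 1024):
            inter, _ = ct.ellipse_overlap(self._unit_circle((0, 0)),
                                          self._unit_circle((1, 0)), n_vertices=nv)
            errs.append(abs(inter - lens) / lens)
        assert errs[1] < 1e-3 and errs[2] < errs[0]
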