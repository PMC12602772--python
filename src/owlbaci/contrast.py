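"""Posterior-overlap contrasts and habitat-niche segregation analysis.

Removal effects are assessed by the overlap of two posterior distributions on
the logit scale (e.g. occupancy at removal sites before vs. after removal):
the overlapping index is the integral of the pointwise minimum of the two
kernel density estimates, and an overlap under 15% is read as a biologically
meaningful difference.

Niche segregation between the invader and each native species is summarized
with (i) a logistic occurrence model for the invader on standardized
elevation, ruggedness and the intermediate-to-late seral fraction, with
average marginal effects, and (ii) 85% standard ellipses (Gaussian quantile
ellipses) of the conditions at each species' detection sites — the ellipse
area measures niche breadth and pairwise intersection measures overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from shapely.geometry import Polygon

from ._util import expit

__all__ = [
    "OverlapResult",
    "EllipseSummary",
    "OccurrenceFit",
    "posterior_overlap",
    "removal_contrasts",
    "fit_occurrence_logistic",
    "average_marginal_effect",
    "standard_ellipse",
    "ellipse_overlap",
]

OVERLAP_THRESHOLD = 0.15


@dataclass
class OverlapResult:
    overlap: float
    scale: str = "logit"
    threshold: float = OVERLAP_THRESHOLD

    @property
    def meaningful(self) -> bool:
        """True when the distributions are distinct enough to matter."""
        return self.overlap < self.threshold


def posterior_overlap(draws_a, draws_b, scale: str = "logit",
                      grid_size: int = 512) -> OverlapResult:
    """Overlapping index of two posterior samples.

    Kernel density estimates (Gaussian, Silverman bandwidth) are evaluated on
    a shared grid spanning both samples plus three bandwidths; the overlap is
    the trapezoid integral of min(f_a, f_b), each density renormalized on the
    grid. Symmetric in its arguments and invariant to a common shift.
    """
    a = np.asarray(draws_a, dtype=float).ravel()
    b = np.asarray(draws_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2 or a.std() == 0 or b.std() == 0:
        raise ValueError("overlap requires non-degenerate draw sets")
    ka = stats.gaussian_kde(a, bw_method="silverman")
    kb = stats.gaussian_kde(b, bw_method="silverman")
    bw = max(ka.factor * a.std(), kb.factor * b.std())
    lo = min(a.min(), b.min()) - 3 * bw
    hi = max(a.max(), b.max()) + 3 * bw
    grid = np.linspace(lo, hi, grid_size)
    fa, fb = ka(grid), kb(grid)
    fa = fa / np.trapezoid(fa, grid)
    fb = fb / np.trapezoid(fb, grid)
    ov = float(np.trapezoid(np.minimum(fa, fb), grid))
    return OverlapResult(min(ov, 1.0), scale=scale)


def removal_contrasts(draws, model_id: str) -> dict[str, OverlapResult]:
    """Pre- vs post-removal contrasts at removal sites, on the logit scale.

    The pre-removal linear predictor is beta0 + beta_site_type; each
    post-removal predictor adds the corresponding removal-phase coefficient
    (allpostlethal for the time-constant model; lethal1/2/3plus for the
    time-dependent one).
    """
    cols = draws.psi_cols
    beta = draws.stacked("beta")
    if "site_type" not in cols:
        raise ValueError(f"model {model_id!r} has no removal site-type term")
    pre = beta[:, 0] + beta[:, cols.index("site_type")]
    post_terms = [c for c in ("allpostlethal", "lethal1", "lethal2", "lethal3plus")
                  if c in cols]
    return {c: posterior_overlap(pre, pre + beta[:, cols.index(c)]) for c in post_terms}


# ---------------------------------------------------------------------------
# Invader occurrence model


@dataclass
class OccurrenceFit:
    params: pd.Series
    bse: pd.Series
    ci: pd.DataFrame
    flagged: bool
    X: pd.DataFrame
    y: np.ndarray


def fit_occurrence_logistic(occurrence, covariates: pd.DataFrame,
                            level: float = 0.85) -> OccurrenceFit:
    """Maximum-likelihood logistic regression of hexagon-level occurrence on
    habitat covariates (single visit, detection near one). Separation falls
    back to a small-ridge penalized fit, flagged."""
    y = np.asarray(occurrence, dtype=float)
    if y.min() == y.max():
        raise ValueError("occurrence outcome is constant; model is undefined")
    X = sm.add_constant(covariates.astype(float), has_constant="add")
    flagged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = res.params
            bse = res.bse
            if not np.all(np.isfinite(params)) or params.abs().max() > 15:
                raise RuntimeError("separation")
        except Exception:
            from .calibration import _ridge_logit

            b = _ridge_logit(X.to_numpy(), y, 1e-3)
            params = pd.Series(b, index=X.columns)
            p = expit(X.to_numpy() @ b)
            w = np.clip(p * (1 - p), 1e-10, None)
            cov_mat = np.linalg.inv((X.to_numpy().T * w) @ X.to_numpy() + 1e-3 * np.eye(X.shape[1]))
            bse = pd.Series(np.sqrt(np.diag(cov_mat)), index=X.columns)
            flagged = True
    zq = stats.norm.ppf(0.5 + level / 2)
    ci = pd.DataFrame({"lo": params - zq * bse, "hi": params + zq * bse})
    return OccurrenceFit(params, bse, ci, flagged, X, y)


def average_marginal_effect(fit: OccurrenceFit, covariate: str,
                            data: pd.DataFrame | None = None) -> float:
    """AME of a continuous covariate: mean over observed rows of
    beta_j * p(x) * (1 - p(x))."""
    if covariate not in fit.params.index:
        raise ValueError(f"unknown covariate {covariate!r}")
    X = fit.X if data is None else sm.add_constant(data.astype(float), has_constant="add")
    p = expit(X.to_numpy() @ fit.params.to_numpy())
    return float(fit.params[covariate] * np.mean(p * (1 - p)))


# ---------------------------------------------------------------------------
# Standard ellipses


@dataclass
class EllipseSummary:
    center: np.ndarray
    cov: np.ndarray
    level: float
    species: str = ""

    @property
    def area(self) -> float:
        c = stats.chi2.ppf(self.level, df=2)
        return float(np.pi * c * np.sqrt(np.linalg.det(self.cov)))

    def boundary(self, n_vertices: int = 256) -> np.ndarray:
        c = stats.chi2.ppf(self.level, df=2)
        L = np.linalg.cholesky(self.cov)
        theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        return self.center + np.sqrt(c) * circle @ L.T

    def polygon(self, n_vertices: int = 256) -> Polygon:
        return Polygon(self.boundary(n_vertices))

    def contains(self, points) -> np.ndarray:
        d = np.asarray(points, dtype=float) - self.center
        inv = np.linalg.inv(self.cov)
        md2 = np.einsum("ij,jk,ik->i", d, inv, d)
        return md2 <= stats.chi2.ppf(self.level, df=2)


def standard_ellipse(points, level: float = 0.85, species: str = "") -> EllipseSummary:
    """Gaussian quantile ellipse of 2-D points: center = mean, shape = sample
    covariance scaled by the chi-square(2) quantile of ``level``."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 two-dimensional points")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    c = np.cov(pts, rowvar=False)
    if np.linalg.det(c) <= 1e-12 * max(np.trace(c) ** 2, 1e-300):
        raise ValueError("points are (near-)collinear; ellipse is degenerate")
    return EllipseSummary(pts.mean(axis=0), c, level, species)


def ellipse_overlap(a: EllipseSummary, b: EllipseSummary,
                    n_vertices: int = 512) -> tuple[float, float]:
    """(intersection area, fraction of the smaller ellipse) via polygonal
    approximation of each boundary and polygon clipping."""
    inter = a.polygon(n_vertices).intersection(b.polygon(n_vertices)).area
    frac = inter / min(a.area, b.area)
    return float(inter), float(min(frac, 1.0))
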