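"""Detector-score threshold calibration against a weekly false-positive bound.

An acoustic classifier emits a prediction score in [0, 1] every few seconds.
To turn score streams into detection/non-detection data one must pick a
minimum score threshold per species such that false positives are rare at the
scale of the occupancy model's repeat-survey unit (a week of nocturnal
recording, n = 84 h). The procedure, following the validated-hour design used
in regional owl monitoring:

1. A validation set of hour-long samples is labelled 1 if the hour contains at
   least one confirmed true positive, else 0 (a flagged hour with no true
   positive is a false-positive hour).
2. For each candidate threshold, the number of predictions in the hour with
   score >= threshold is the predictor in a logistic regression of
   false-positive status (FP = 1, TP = 0).
3. The fitted hourly FP probability is scaled to a weekly rate via
   ``1 - (1 - FP)**n`` and the smallest threshold whose weekly rate is under
   the target (default 1%) is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from ._util import expit

__all__ = [
    "THRESHOLD_LADDER",
    "HourSample",
    "HourlyFPFit",
    "CalibrationResult",
    "count_above",
    "fit_hourly_fp",
    "weekly_fp",
    "select_threshold",
    "calibrate",
]

#: Candidate score thresholds: 0.1..0.9 by 0.1, then 0.91..0.99 by 0.01.
THRESHOLD_LADDER = np.round(
    np.concatenate([np.arange(1, 10) / 10.0, np.arange(91, 100) / 100.0]), 2
)

# Parameters whose absolute value exceeds this are taken as evidence of
# (quasi-)complete separation in the unpenalized fit.
_SEPARATION_BOUND = 15.0
_RIDGE_PENALTY = 1e-4


@dataclass
class HourSample:
    """One labelled validation hour: scores of every prediction in the hour."""

    aru_id: str
    hour_start: str
    label: int  # 1 = contains >=1 confirmed true positive
    scores: np.ndarray

    def counts(self, thresholds: np.ndarray) -> np.ndarray:
        return count_above(self.scores, thresholds)


@dataclass
class HourlyFPFit:
    threshold: float
    intercept: float
    slope: float
    fp_hourly: float
    reference_count: float
    flagged: bool = False  # True when the ridge fallback was used


@dataclass
class CalibrationResult:
    thresholds: np.ndarray
    fp_hourly: np.ndarray
    fp_weekly: np.ndarray
    flags: np.ndarray
    target: float
    n_hours: int
    selected: float | None = None
    fits: list[HourlyFPFit] = field(default_factory=list)

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "fp_hourly": self.fp_hourly,
                "fp_weekly": self.fp_weekly,
                "separation_flag": self.flags,
            }
        )


def count_above(scores, thresholds) -> np.ndarray:
    """Number of scores >= each threshold; non-increasing in the threshold."""
    scores = np.asarray(scores, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("threshold list is empty")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    s = np.sort(scores)
    return (s.size - np.searchsorted(s, thresholds, side="left")).astype(int)


def _ridge_logit(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Newton solve of the L2-penalized logistic; small lam keeps the fit
    close to the MLE while pinning separated coefficients to finite values."""
    beta = np.zeros(X.shape[1])
    for _ in range(200):
        eta = X @ beta
        p = expit(eta)
        grad = X.T @ (y - p) - lam * beta
        w = np.clip(p * (1 - p), 1e-10, None)
        hess = (X.T * w) @ X + lam * np.eye(X.shape[1])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def fit_hourly_fp(
    samples: list[HourSample],
    threshold: float,
    reference_count: float | str = 1,
) -> HourlyFPFit:
    """Logistic model of FP status (1 = no confirmed true positive) on the
    number of predictions above ``threshold``; returns the hourly FP
    probability evaluated at ``reference_count`` predictions (default 1, the
    minimal flagged hour; pass ``"mean"`` for the mean observed count).
    """
    if len(samples) < 2:
        raise ValueError("need at least two labelled hour samples")
    labels = np.array([s.label for s in samples], dtype=float)
    if labels.min() == labels.max():
        raise ValueError(
            "degenerate validation set: all hours share one label; "
            "cannot fit the FP status model"
        )
    counts = np.array(
        [count_above(s.scores, np.array([threshold]))[0] for s in samples],
        dtype=float,
    )
    # FP status: hour flagged as containing the species but with no true
    # positive. Response is 1 for false-positive hours.
    y = 1.0 - labels
    ref = float(np.mean(counts)) if reference_count == "mean" else float(reference_count)

    if counts.min() == counts.max():
        # Constant predictor: the two-column design is singular, so the model
        # collapses to an intercept-only fit (slope identically 0) and the FP
        # probability is the observed FP fraction.
        frac = float(np.mean(y))
        return HourlyFPFit(threshold, float(np.log(frac / (1 - frac))), 0.0, frac, ref)

    X = np.column_stack([np.ones_like(counts), counts])
    flagged = False
    params = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = res.params
            if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > _SEPARATION_BOUND:
                params = None
        except Exception:
            params = None
    if params is None:
        params = _ridge_logit(X, y, _RIDGE_PENALTY)
        flagged = True
    fp = float(expit(params[0] + params[1] * ref))
    return HourlyFPFit(threshold, float(params[0]), float(params[1]), fp, ref, flagged)


def weekly_fp(hourly_fp: float, n_hours: int = 84) -> float:
    """Probability of >=1 false positive in a secondary sampling period:
    ``1 - (1 - FP)**n`` with n the surveyed hours per period (84 = 12 nocturnal
    hours x 7 nights)."""
    if not 0.0 <= hourly_fp <= 1.0:
        raise ValueError("hourly_fp must lie in [0, 1]")
    if n_hours < 1:
        raise ValueError("n_hours must be >= 1")
    if hourly_fp == 1.0:
        return 1.0
    return float(-np.expm1(n_hours * np.log1p(-hourly_fp)))


def select_threshold(calibration: CalibrationResult, target: float | None = None) -> float:
    """Smallest threshold whose weekly FP rate is strictly below the target
    (the smallest qualifying threshold retains the most true detections)."""
    target = calibration.target if target is None else target
    ok = calibration.fp_weekly < target
    if not np.any(ok):
        best = float(calibration.fp_weekly.min())
        raise ValueError(
            f"no threshold achieves weekly FP < {target:g}; "
            f"best achievable rate is {best:.4g}"
        )
    return float(calibration.thresholds[np.argmax(ok)])


def calibrate(
    samples: list[HourSample],
    thresholds: np.ndarray | None = None,
    target: float = 0.01,
    n_hours: int = 84,
    reference_count: float | str = 1,
) -> CalibrationResult:
    """Run the full calibration over a threshold ladder and select a threshold."""
    thresholds = THRESHOLD_LADDER if thresholds is None else np.asarray(thresholds, float)
    fits = [fit_hourly_fp(samples, float(t), reference_count) for t in thresholds]
    fp_hourly = np.array([f.fp_hourly for f in fits])
    fp_week = np.array([weekly_fp(f, n_hours) for f in fp_hourly])
    flags = np.array([f.flagged for f in fits])
    result = CalibrationResult(thresholds, fp_hourly, fp_week, flags, target, n_hours, fits=fits)
    result.selected = select_threshold(result)
    return result
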