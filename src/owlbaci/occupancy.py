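"""Bayesian stacked single-season occupancy models with imperfect detection.

Model. Each unit-season row i has latent occupancy z_i ~ Bernoulli(psi_i),

    logit psi_i = x_i' beta + u_year[t(i)] + u_site[s(i)],

with year and site random effects u ~ Normal(0, sigma^2) absorbing the
repeated structure created by stacking seasons, and weekly detections

    y_it | z_i ~ Bernoulli(z_i * p_it),    logit p_it = w_it' alpha,

where w contains the five detection predictors (standardized ordinal date,
survey-year category, standardized ruggedness, standardized weekly recording
hours, invader presence). Marginalizing z gives the site likelihood

    L_i = psi_i * prod_t p_it^y (1-p_it)^(1-y)          if any detection,
    L_i = psi_i * prod_t (1-p_it) + (1 - psi_i)          otherwise,

with unsurveyed (missing) periods dropped (within-season closure).

Six fixed-effect structures express the BACI design (fire / removal /
interaction, each time-constant or time-dependent); see ``MODEL_COLUMNS``.

Inference is by adaptive random-walk Metropolis-within-Gibbs over beta,
alpha, the random effects (element-wise, vectorized per block), and the
random-effect SDs, with weakly informative Normal(0, 2.5^2) priors on the
coefficients and half-Normal(0, 1) on the SDs. Proposal scales adapt during
burn-in only. Convergence is assessed with the Gelman-Rubin potential scale
reduction factor and fit with a MacKenzie-Bailey posterior predictive check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy.special import log_expit

from ._util import expit, split_rngs

__all__ = [
    "MODEL_COLUMNS",
    "OccupancyDesign",
    "Priors",
    "PosteriorDraws",
    "build_design",
    "site_log_likelihood",
    "sample_posterior",
    "gelman_rubin",
    "mb_gof",
    "predict_occupancy",
]

#: Occupancy fixed-effect columns (after the intercept) for the six models.
MODEL_COLUMNS = {
    "fire_tc": ["burn", "allpostburn"],
    "fire_td": ["burn", "burn1", "burn2", "burn3"],
    "bo_tc": ["site_type", "allpostlethal"],
    "bo_td": ["site_type", "lethal1", "lethal2", "lethal3plus"],
    "int_tc": ["site_type", "burn", "postlethal_x_burnyrs"],
    "int_td": ["site_type", "burn", "postlethal_x_burn1",
               "postlethal_x_burn2", "postlethal_x_burn3"],
}


@dataclass
class OccupancyDesign:
    y: np.ndarray            # (n, T) 0/1 with NaN = not surveyed
    X_psi: np.ndarray        # (n, k) occupancy design, intercept first
    X_p: np.ndarray          # (n, T, m) detection design
    year_idx: np.ndarray     # (n,) dense 0..K-1
    site_idx: np.ndarray     # (n,) dense 0..S-1
    psi_cols: list = field(default_factory=list)
    p_cols: list = field(default_factory=list)
    units: np.ndarray | None = None
    seasons: np.ndarray | None = None

    @property
    def n_years(self):
        return int(self.year_idx.max()) + 1

    @property
    def n_sites(self):
        return int(self.site_idx.max()) + 1

    @property
    def mask(self):
        return ~np.isnan(self.y)


@dataclass
class Priors:
    beta_sd: float = 2.5
    alpha_sd: float = 2.5
    sigma_sd: float = 1.0  # half-Normal scale for random-effect SDs
    flat: bool = False     # improper flat prior on coefficients (tests)


def build_design(model_id: str, covariates: pd.DataFrame, history) -> OccupancyDesign:
    """Assemble the stacked design for one model from the covariate table and
    an encounter history (rows matched on unit & season).

    Occupancy columns are exactly the equation's: indicators and severity
    fractions enter raw (they are already on an interpretable 0-1 scale);
    continuous detection covariates are standardized.
    """
    if model_id not in MODEL_COLUMNS:
        raise ValueError(f"unknown model_id {model_id!r}")
    hdf = history.df if hasattr(history, "df") else history
    T = sum(c.startswith("y") and c[1:].isdigit() for c in hdf.columns)
    merged = hdf.merge(covariates, on=["unit", "season"], how="left", validate="one_to_one")
    for c in MODEL_COLUMNS[model_id] + ["ruggedness"]:
        if c not in merged.columns or merged[c].isna().any():
            raise ValueError(f"missing covariate column {c!r} for model {model_id!r}")

    y = merged[[f"y{k}" for k in range(1, T + 1)]].to_numpy(float)
    eff = merged[[f"e{k}" for k in range(1, T + 1)]].to_numpy(float)
    X_psi = np.column_stack(
        [np.ones(len(merged))] + [merged[c].to_numpy(float) for c in MODEL_COLUMNS[model_id]]
    )

    def z(v):
        sd = np.nanstd(v)
        return (v - np.nanmean(v)) / (sd if sd > 0 else 1.0)

    date_mid = np.arange(1, T + 1) * 7.0 - 3.5
    date_s = (date_mid - date_mid.mean()) / date_mid.std()
    seasons = np.sort(merged["season"].unique())
    year_codes = merged["season"].map({s: i for i, s in enumerate(seasons)}).to_numpy()
    rug_s = z(merged["ruggedness"].to_numpy(float))
    hours_s = z(np.where(eff > 0, eff, np.nan))
    invader = merged["invader"].to_numpy(float) if "invader" in merged else np.zeros(len(merged))

    n = len(merged)
    p_cols = ["(intercept)", "date"] + [f"year_{s}" for s in seasons[1:]] + [
        "ruggedness", "hours", "invader"]
    m = len(p_cols)
    X_p = np.zeros((n, T, m))
    X_p[:, :, 0] = 1.0
    X_p[:, :, 1] = date_s[None, :]
    for j in range(1, len(seasons)):
        X_p[:, :, 1 + j] = (year_codes == j)[:, None]
    X_p[:, :, m - 3] = rug_s[:, None]
    X_p[:, :, m - 2] = np.nan_to_num(hours_s)
    X_p[:, :, m - 1] = invader[:, None]
    X_p[np.isnan(y)] = np.nan

    units = merged["unit"].to_numpy()
    uniq = pd.unique(units)
    site_idx = pd.Series(units).map({u: i for i, u in enumerate(uniq)}).to_numpy()
    return OccupancyDesign(
        y=y, X_psi=X_psi, X_p=X_p, year_idx=year_codes.astype(int),
        site_idx=site_idx.astype(int),
        psi_cols=["(intercept)"] + MODEL_COLUMNS[model_id], p_cols=p_cols,
        units=units, seasons=merged["season"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Likelihood


def _row_loglik(eta_psi, det_ll, nodet_ll, any_det):
    """Vectorized site log-likelihoods given cached detection sums."""
    lpsi = log_expit(eta_psi)
    l1mpsi = log_expit(-eta_psi)
    return np.where(any_det, lpsi + det_ll, np.logaddexp(lpsi + nodet_ll, l1mpsi))


def _detection_cache(y, eta_p):
    mask = ~np.isnan(y)
    with np.errstate(invalid="ignore"):
        lp = log_expit(eta_p)
        l1mp = log_expit(-eta_p)
        det = np.where(mask, np.where(y == 1, lp, l1mp), 0.0).sum(axis=1)
        nodet = np.where(mask, l1mp, 0.0).sum(axis=1)
    any_det = np.nansum(y == 1, axis=1) > 0
    return det, nodet, any_det


def site_log_likelihood(psi, p, y):
    """Log-probability of one site's encounter history.

    psi is scalar; p and y are per-period arrays, with NaN in y marking
    unsurveyed periods (p is ignored there). The latent occupancy state is
    marginalized out.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if not np.all(np.isfinite(psi)) or not 0 <= psi <= 1:
        raise ValueError("psi must be a finite probability")
    obs = ~np.isnan(y)
    if not np.all(np.isfinite(p[obs])):
        raise ValueError("non-finite detection probability in surveyed period")
    yo, po = y[obs], p[obs]
    with np.errstate(divide="ignore"):
        if np.any(yo == 1):
            return float(np.log(psi) + np.sum(np.where(yo == 1, np.log(po), np.log1p(-po))))
        return float(np.logaddexp(
            np.log(psi) + np.sum(np.log1p(-po)) if psi > 0 else -np.inf,
            np.log1p(-psi) if psi < 1 else -np.inf,
        ))


# ---------------------------------------------------------------------------
# Sampler


@dataclass
class PosteriorDraws:
    """MCMC draws, shape (chains, kept iterations, dim)."""

    beta: np.ndarray
    alpha: np.ndarray | None
    u_year: np.ndarray | None
    u_site: np.ndarray | None
    sigma_year: np.ndarray | None
    sigma_site: np.ndarray | None
    psi_cols: list
    p_cols: list
    burn: int

    def stacked(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        if arr is None:
            raise ValueError(f"no draws for {name}")
        return arr.reshape(-1, arr.shape[-1]) if arr.ndim == 3 else arr.reshape(-1)

    def summary(self, level: float = 0.85) -> pd.DataFrame:
        lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
        rows = []
        for name, cols in (("beta", self.psi_cols), ("alpha", self.p_cols)):
            arr = getattr(self, name)
            if arr is None:
                continue
            flat = arr.reshape(-1, arr.shape[-1])
            for j, c in enumerate(cols):
                rows.append({
                    "param": f"{name}[{c}]", "mean": flat[:, j].mean(),
                    "sd": flat[:, j].std(),
                    f"ci{int(level*100)}_lo": np.percentile(flat[:, j], lo),
                    f"ci{int(level*100)}_hi": np.percentile(flat[:, j], hi),
                })
        for name in ("sigma_year", "sigma_site"):
            arr = getattr(self, name)
            if arr is not None:
                flat = arr.reshape(-1)
                rows.append({
                    "param": name, "mean": flat.mean(), "sd": flat.std(),
                    f"ci{int(level*100)}_lo": np.percentile(flat, lo),
                    f"ci{int(level*100)}_hi": np.percentile(flat, hi),
                })
        return pd.DataFrame(rows)

    def rhat(self) -> dict:
        out = {}
        for name, cols in (("beta", self.psi_cols), ("alpha", self.p_cols)):
            arr = getattr(self, name)
            if arr is None:
                continue
            for j, c in enumerate(cols):
                out[f"{name}[{c}]"] = gelman_rubin(arr[:, :, j])
        for name in ("sigma_year", "sigma_site"):
            arr = getattr(self, name)
            if arr is not None:
                out[name] = gelman_rubin(arr)
        return out


def _halfnormal_logpdf(x, sd):
    return -0.5 * (x / sd) ** 2


class _Chain:
    """One adaptive Metropolis-within-Gibbs chain over the stacked model."""

    def __init__(self, design: OccupancyDesign, priors: Priors, rng,
                 fixed_p, random_effects):
        self.d = design
        self.priors = priors
        self.rng = rng
        self.fixed_p = fixed_p
        self.re = random_effects
        n, k = design.X_psi.shape
        self.beta = np.zeros(k)
        self.m = design.X_p.shape[2]
        self.alpha = np.zeros(self.m)
        self.uy = np.zeros(design.n_years)
        self.us = np.zeros(design.n_sites)
        self.sy = 0.5
        self.ss = 0.5
        self.s_beta = np.full(k, 0.3)
        self.s_alpha = np.full(self.m, 0.3)
        self.s_uy = 0.3
        self.s_us = 0.5
        self.s_sig = 0.5
        self._refresh_detection()
        self._refresh_psi_eta()

    # -- caches ------------------------------------------------------------
    def _refresh_detection(self):
        if self.fixed_p is not None:
            p = np.broadcast_to(np.asarray(self.fixed_p, float), self.d.y.shape)
            mask = self.d.mask
            with np.errstate(divide="ignore", invalid="ignore"):
                lp, l1mp = np.log(p), np.log1p(-p)
            y = self.d.y
            det = np.where(mask, np.where(y == 1, lp, l1mp), 0.0)
            det = np.where(np.isfinite(det), det, -1e300).sum(axis=1)
            nodet = np.where(mask, l1mp, 0.0)
            nodet = np.where(np.isfinite(nodet), nodet, -1e300).sum(axis=1)
            self.det, self.nodet = det, nodet
            self.any_det = np.nansum(y == 1, axis=1) > 0
        else:
            self.eta_p = np.einsum("ntm,m->nt", np.nan_to_num(self.d.X_p), self.alpha)
            self.det, self.nodet, self.any_det = _detection_cache(self.d.y, self.eta_p)

    def _refresh_psi_eta(self):
        self.eta_psi = (self.d.X_psi @ self.beta
                        + self.uy[self.d.year_idx] + self.us[self.d.site_idx])
        self.ll_rows = _row_loglik(self.eta_psi, self.det, self.nodet, self.any_det)

    # -- priors ------------------------------------------------------------
    def _coef_logprior(self, v, sd):
        if self.priors.flat:
            return 0.0
        return float(-0.5 * np.sum((v / sd) ** 2))

    # -- updates -----------------------------------------------------------
    def update_beta(self, adapt, t):
        for j in range(len(self.beta)):
            prop = self.beta[j] + self.rng.normal(0, self.s_beta[j])
            delta_eta = self.d.X_psi[:, j] * (prop - self.beta[j])
            new_eta = self.eta_psi + delta_eta
            new_ll = _row_loglik(new_eta, self.det, self.nodet, self.any_det)
            lr = (new_ll.sum() - self.ll_rows.sum()
                  + self._coef_logprior(prop, self.priors.beta_sd)
                  - self._coef_logprior(self.beta[j], self.priors.beta_sd))
            acc = np.log(self.rng.random()) < lr
            if acc:
                self.beta[j] = prop
                self.eta_psi = new_eta
                self.ll_rows = new_ll
            if adapt:
                self.s_beta[j] *= np.exp((float(acc) - 0.44) / np.sqrt(t + 1))

    def update_alpha(self, adapt, t):
        if self.fixed_p is not None:
            return
        Xp = np.nan_to_num(self.d.X_p)
        for j in range(self.m):
            step = self.rng.normal(0, self.s_alpha[j])
            eta_p = self.eta_p + Xp[:, :, j] * step
            det, nodet, any_det = _detection_cache(self.d.y, eta_p)
            new_ll = _row_loglik(self.eta_psi, det, nodet, any_det)
            lr = (new_ll.sum() - self.ll_rows.sum()
                  + self._coef_logprior(self.alpha[j] + step, self.priors.alpha_sd)
                  - self._coef_logprior(self.alpha[j], self.priors.alpha_sd))
            acc = np.log(self.rng.random()) < lr
            if acc:
                self.alpha[j] += step
                self.eta_p = eta_p
                self.det, self.nodet, self.any_det = det, nodet, any_det
                self.ll_rows = new_ll
            if adapt:
                self.s_alpha[j] *= np.exp((float(acc) - 0.44) / np.sqrt(t + 1))

    def _update_effects(self, u, sigma, idx, n_groups, scale, adapt, t):
        prop = u + self.rng.normal(0, scale, n_groups)
        new_eta = self.eta_psi + (prop - u)[idx]
        new_ll = _row_loglik(new_eta, self.det, self.nodet, self.any_det)
        d_data = np.bincount(idx, weights=new_ll - self.ll_rows, minlength=n_groups)
        d_prior = -0.5 * (prop**2 - u**2) / sigma**2
        acc = np.log(self.rng.random(n_groups)) < d_data + d_prior
        u_new = np.where(acc, prop, u)
        self.eta_psi += (u_new - u)[idx]
        self.ll_rows = _row_loglik(self.eta_psi, self.det, self.nodet, self.any_det)
        new_scale = scale * np.exp((acc.mean() - 0.44) / np.sqrt(t + 1)) if adapt else scale
        return u_new, new_scale

    def _update_sigma(self, sigma, u, adapt, t):
        prop = sigma * np.exp(self.rng.normal(0, self.s_sig))
        lr = (
            len(u) * (np.log(sigma) - np.log(prop))
            - 0.5 * np.sum(u**2) * (1 / prop**2 - 1 / sigma**2)
            + _halfnormal_logpdf(prop, self.priors.sigma_sd)
            - _halfnormal_logpdf(sigma, self.priors.sigma_sd)
            + np.log(prop) - np.log(sigma)  # log-scale proposal Jacobian
        )
        acc = np.log(self.rng.random()) < lr
        new = prop if acc else sigma
        if adapt:
            self.s_sig *= np.exp((float(acc) - 0.44) / np.sqrt(t + 1))
        return new

    def _rescale_move(self, u, sigma, idx):
        """Joint rescale (u, sigma) -> (c*u, c*sigma): the standardized
        effects are invariant, so this moves sigma even when the individual
        effects mix slowly. Acceptance reduces to the data likelihood ratio
        times the prior ratio for sigma on the log scale."""
        c = np.exp(self.rng.normal(0, 0.3))
        new_u = c * u
        new_eta = self.eta_psi + (new_u - u)[idx]
        new_ll = _row_loglik(new_eta, self.det, self.nodet, self.any_det)
        new_sigma = c * sigma
        lr = (new_ll.sum() - self.ll_rows.sum()
              + _halfnormal_logpdf(new_sigma, self.priors.sigma_sd)
              - _halfnormal_logpdf(sigma, self.priors.sigma_sd)
              + np.log(new_sigma) - np.log(sigma))
        if np.log(self.rng.random()) < lr:
            self.eta_psi = new_eta
            self.ll_rows = new_ll
            return new_u, new_sigma
        return u, sigma

    def sweep(self, adapt, t):
        self.update_beta(adapt, t)
        self.update_alpha(adapt, t)
        if self.re:
            self.uy, self.s_uy = self._update_effects(
                self.uy, self.sy, self.d.year_idx, self.d.n_years, self.s_uy, adapt, t)
            self.us, self.s_us = self._update_effects(
                self.us, self.ss, self.d.site_idx, self.d.n_sites, self.s_us, adapt, t)
            self.sy = self._update_sigma(self.sy, self.uy, adapt, t)
            self.ss = self._update_sigma(self.ss, self.us, adapt, t)
            self.uy, self.sy = self._rescale_move(self.uy, self.sy, self.d.year_idx)
            self.us, self.ss = self._rescale_move(self.us, self.ss, self.d.site_idx)


def sample_posterior(
    design: OccupancyDesign,
    priors: Priors | None = None,
    chains: int = 4,
    iters: int = 2600,
    burn: int | None = None,
    seed: int = 0,
    fixed_p=None,
    random_effects: bool = True,
) -> PosteriorDraws:
    """Run the adaptive Metropolis-within-Gibbs sampler.

    ``burn`` defaults to half the iterations (discarded; adaptation happens
    only there). ``fixed_p`` pins the detection probability (testing hook).
    Draw arrays have shape (chains, iters - burn, dim).
    """
    priors = priors or Priors()
    burn = iters // 2 if burn is None else burn
    if not np.all(design.X_psi.std(axis=0)[1:] > 0):
        raise ValueError("occupancy design has a constant non-intercept column")
    rngs = split_rngs(seed, chains)
    kept = iters - burn
    k = design.X_psi.shape[1]
    m = design.X_p.shape[2]
    out_beta = np.empty((chains, kept, k))
    out_alpha = np.empty((chains, kept, m)) if fixed_p is None else None
    out_uy = np.empty((chains, kept, design.n_years)) if random_effects else None
    out_us = np.empty((chains, kept, design.n_sites)) if random_effects else None
    out_sy = np.empty((chains, kept)) if random_effects else None
    out_ss = np.empty((chains, kept)) if random_effects else None
    for c in range(chains):
        ch = _Chain(design, priors, rngs[c], fixed_p, random_effects)
        for t in range(iters):
            ch.sweep(adapt=t < burn, t=t)
            if t >= burn:
                i = t - burn
                out_beta[c, i] = ch.beta
                if out_alpha is not None:
                    out_alpha[c, i] = ch.alpha
                if random_effects:
                    out_uy[c, i] = ch.uy
                    out_us[c, i] = ch.us
                    out_sy[c, i] = ch.sy
                    out_ss[c, i] = ch.ss
    return PosteriorDraws(out_beta, out_alpha, out_uy, out_us, out_sy, out_ss,
                          list(design.psi_cols), list(design.p_cols), burn)


# ---------------------------------------------------------------------------
# Diagnostics


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor for one parameter, chains x draws."""
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = x.shape
    means = x.mean(axis=1)
    B = n * means.var(ddof=1)
    W = x.var(axis=1, ddof=1).mean()
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def _history_stat(y, psi, p, pool_below=2.0):
    """MacKenzie-Bailey Pearson chi-square over encounter-history frequencies,
    cohorted by missingness pattern; within each cohort, observed histories
    with expected count < ``pool_below`` are pooled together with the
    unobserved-history remainder mass."""
    mask = ~np.isnan(y)
    stat = 0.0
    patterns = {}
    for i in range(y.shape[0]):
        patterns.setdefault(tuple(mask[i]), []).append(i)
    for pat, idx in patterns.items():
        obs_cols = np.array(pat)
        if not obs_cols.any():
            continue
        idx = np.array(idx)
        sub_y = y[np.ix_(idx, np.nonzero(obs_cols)[0])]
        sub_p = p[np.ix_(idx, np.nonzero(obs_cols)[0])]
        sub_psi = psi[idx]
        hist, counts = np.unique(sub_y, axis=0, return_counts=True)
        # P(history h | row params): (rows, histories)
        ph = np.prod(np.where(hist[None, :, :] == 1, sub_p[:, None, :],
                              1 - sub_p[:, None, :]), axis=2)
        anyd = hist.sum(axis=1) > 0
        prob = sub_psi[:, None] * ph
        prob[:, ~anyd] += (1 - sub_psi)[:, None]
        E = prob.sum(axis=0)
        O = counts.astype(float)
        N = len(idx)
        big = E >= pool_below
        stat += float(np.sum((O[big] - E[big]) ** 2 / E[big]))
        # pooled: small-E observed histories + all unobserved histories
        O_pool = float(O[~big].sum())
        E_pool = float(E[~big].sum()) + max(N - float(E.sum()), 0.0)
        if E_pool > 0:
            stat += (O_pool - E_pool) ** 2 / E_pool
    return stat


def mb_gof(draws: PosteriorDraws, design: OccupancyDesign, n_rep: int = 100,
           seed: int = 0) -> dict:
    """Posterior-predictive goodness of fit.

    For each of ``n_rep`` posterior draws: compute the chi-square discrepancy
    of the observed histories and of a replicate dataset simulated from that
    draw; the Bayesian p-value is the fraction of replicates whose statistic
    is at least the observed one.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = default_rng(seed)
    beta_flat = draws.stacked("beta")
    total = beta_flat.shape[0]
    pick = rng.choice(total, size=min(n_rep, total), replace=False)
    alpha_flat = draws.stacked("alpha") if draws.alpha is not None else None
    uy_flat = draws.stacked("u_year") if draws.u_year is not None else None
    us_flat = draws.stacked("u_site") if draws.u_site is not None else None
    mask = design.mask
    Xp = np.nan_to_num(design.X_p)
    t_obs, t_rep = [], []
    for j in pick:
        eta_psi = design.X_psi @ beta_flat[j]
        if uy_flat is not None:
            eta_psi = eta_psi + uy_flat[j][design.year_idx] + us_flat[j][design.site_idx]
        psi = expit(eta_psi)
        p = expit(np.einsum("ntm,m->nt", Xp, alpha_flat[j])) if alpha_flat is not None \
            else np.broadcast_to(0.5, design.y.shape)
        to = _history_stat(design.y, psi, p)
        z = (rng.random(len(psi)) < psi).astype(float)
        yr = np.where(mask, (rng.random(design.y.shape) < p) * z[:, None], np.nan)
        tr = _history_stat(yr, psi, p)
        t_obs.append(to)
        t_rep.append(tr)
    t_obs, t_rep = np.array(t_obs), np.array(t_rep)
    return {"p_value": float(np.mean(t_rep >= t_obs)),
            "t_obs": t_obs, "t_rep": t_rep}


def predict_occupancy(draws: PosteriorDraws, profile: dict, level: float = 0.85,
                      marginalize: str = "draw", seed: int = 0) -> dict:
    """Posterior occupancy probability at a covariate profile.

    ``profile`` maps occupancy column names (sans intercept) to values; all
    columns of the fitted model must be supplied. Random effects are
    marginalized by drawing fresh effects from the posterior SDs
    (``marginalize="draw"``) or set to zero (``"zero"``).
    """
    cols = draws.psi_cols[1:]
    missing = [c for c in cols if c not in profile]
    if missing:
        raise ValueError(f"profile missing occupancy columns: {missing}")
    x = np.concatenate([[1.0], [float(profile[c]) for c in cols]])
    beta = draws.stacked("beta")
    eta = beta @ x
    if marginalize == "draw" and draws.sigma_year is not None:
        rng = default_rng(seed)
        eta = eta + rng.normal(0, draws.stacked("sigma_year")) \
                  + rng.normal(0, draws.stacked("sigma_site"))
    psi = expit(eta)
    lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    return {"mean": float(psi.mean()),
            "ci": (float(np.percentile(psi, lo)), float(np.percentile(psi, hi))),
            "draws": psi}
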