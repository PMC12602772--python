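"""Synthetic acoustic-survey generator with known ground truth.

Emulates a regional passive acoustic monitoring design: a lattice of 400-ha
hexagonal cells (non-contiguous sample), two recording units per hexagon at
least 500 m apart, four survey seasons with either continuous 5-week or
pulsed 3x1-week deployments, severe-wildfire footprints with a controlled
high-severity fraction, invasive-owl removal locations, latent site-year
occupancy following the BACI model equations, imperfect weekly detection
driven by date / year / ruggedness / effort / invader presence, and hourly
classifier score streams with planted true and false positives.

Everything is planar (meters) and driven by a single integer seed; a fixed
seed gives bit-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy import ndimage, stats

from . import covariates as cov
from ._util import expit
from .calibration import HourSample
from .encounters import N_PERIODS, period_windows, season_start

__all__ = [
    "FireSpec",
    "Landscape",
    "SurveyDesign",
    "TruthParams",
    "SpeciesScoreProfile",
    "simulate_landscape",
    "simulate_survey",
    "simulate_detections",
    "simulate_scores",
    "validation_sample",
    "simulate_fp_weeks",
    "simulate_simple_history",
    "write_outputs",
]

HEX_AREA_M2 = 4.0e6  # 400 ha
HEX_CIRCUMRADIUS = float(np.sqrt(2 * HEX_AREA_M2 / (3 * np.sqrt(3.0))))  # ~1241 m
HEX_SPACING = float(np.sqrt(3.0) * HEX_CIRCUMRADIUS)  # center-to-center, ~2149 m
DEFAULT_SEASONS = (2018, 2021, 2022, 2023)


@dataclass
class FireSpec:
    year: int
    center: tuple[float, float]
    radius: float  # footprint radius, m
    severity_frac: float  # target high-severity fraction inside the footprint


@dataclass
class Landscape:
    cell_size: float
    origin: tuple[float, float]
    elevation: np.ndarray
    seral: np.ndarray
    fires: list[tuple[FireSpec, np.ndarray]]  # (spec, severe-burn 0/1 mask)

    @property
    def extent(self):
        ny, nx = self.elevation.shape
        return (nx * self.cell_size, ny * self.cell_size)


@dataclass
class SurveyDesign:
    hexagons: pd.DataFrame  # hexagon, x, y
    arus: pd.DataFrame  # aru_id, hexagon, x, y
    seasons: list[int]
    deployments: pd.DataFrame  # aru_id, season, start, end


@dataclass
class TruthParams:
    """Generating values for every symbol in the occupancy and detection
    models, plus the disturbance layout."""

    # Occupancy coefficients per model, intercept first, in the column order
    # of occupancy.MODEL_COLUMNS. Defaults give plausible desk-scale rates.
    occupancy_beta: dict = field(default_factory=lambda: {
        "fire_tc": np.array([-1.0, 0.5, -3.0]),
        "fire_td": np.array([-1.0, 0.5, -2.0, -2.5, -3.0]),
        "bo_tc": np.array([-1.2, -1.1, 0.8]),
        "bo_td": np.array([-1.2, -1.1, 0.6, 0.8, 1.0]),
        "int_tc": np.array([-1.0, -1.1, 0.5, -0.5]),
        "int_td": np.array([-1.0, -1.1, 0.5, -0.3, -0.5, -0.7]),
    })
    sigma_year: float = 0.3
    sigma_site: float = 0.3
    # Detection: intercept, standardized ordinal date, per-season shifts,
    # standardized ruggedness, standardized weekly hours, invader presence.
    det_intercept: float = -0.3
    det_date: float = -1.3
    det_year: dict = field(default_factory=lambda: {2018: 0.3, 2021: 0.0, 2022: -0.1, 2023: -0.2})
    det_ruggedness: float = 0.28
    det_hours: float = 0.57
    det_invader: float = 0.34
    # Invading predator occurrence (per hexagon): intercept, std elevation,
    # std ruggedness, seral fraction; removals suppress it afterwards.
    invader_beta: tuple = (-3.4, -0.28, -0.61, 4.21)
    invader_weekly_p: float = 0.7
    invader_post_removal_drop: float = -4.0
    n_removals: int = 12
    removal_year: int = 2019
    removal_placement: str = "preferential"  # or "uniform"
    # Optional extra within-season detection noise (logit-scale SD); off by
    # default — the five predictors are the stated heterogeneity sources.
    extra_p_sd: float = 0.0
    seed: int = 0


@dataclass
class SpeciesScoreProfile:
    """Generative model for one species' hourly classifier score stream.

    True calls arrive as a Poisson process (per hour) with high scores; false
    predictions arrive independently with low-skewed scores.
    """

    true_rate: float = 0.08  # true calls / hour
    fp_rate: float = 5.0  # false predictions / hour
    tp_beta: tuple = (5.0, 1.5)
    fp_beta: tuple = (1.0, 5.0)

    def fp_tail(self, threshold: float) -> float:
        a, b = self.fp_beta
        return float(stats.beta.sf(threshold, a, b))

    def hourly_fp_prob(self, threshold: float) -> float:
        """P(an hour contains >=1 false prediction with score >= threshold)."""
        return float(-np.expm1(-self.fp_rate * self.fp_tail(threshold)))


# ---------------------------------------------------------------------------
# Landscape


def _smooth_field(shape, cell_size, scale_m, rng):
    raw = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(raw, sigma=scale_m / cell_size, mode="reflect")
    return (f - f.mean()) / (f.std() + 1e-12)


def simulate_landscape(
    extent=(24_000.0, 24_000.0),
    cell_size=20.0,
    fire_specs=None,
    seed=0,
    base_elevation=1400.0,
    relief=250.0,
    smooth_scale=400.0,
    seral_target=0.45,
    seral_scale=600.0,
) -> Landscape:
    """Smoothed Gaussian random fields for elevation and forest structure,
    plus clumped severe-burn masks realizing each fire's requested
    high-severity fraction (exact to the cell-count quantile)."""
    rng = default_rng(seed)
    nx = int(round(extent[0] / cell_size))
    ny = int(round(extent[1] / cell_size))
    elevation = base_elevation + relief * _smooth_field((ny, nx), cell_size, smooth_scale, rng)
    sf = _smooth_field((ny, nx), cell_size, seral_scale, rng)
    seral = (sf < np.quantile(sf, seral_target)).astype(np.int8)

    fires = []
    for spec in fire_specs or []:
        if not (0 <= spec.center[0] <= extent[0] and 0 <= spec.center[1] <= extent[1]):
            raise ValueError(f"fire footprint centroid {spec.center} outside extent")
        if not 0.0 <= spec.severity_frac <= 1.0:
            raise ValueError("severity fraction must lie in [0, 1]")
        foot = cov._cells_within((ny, nx), cell_size, (0.0, 0.0), spec.center, spec.radius)
        if not foot.any():
            raise ValueError("fire footprint contains no raster cells")
        mask = np.zeros((ny, nx), dtype=np.int8)
        if spec.severity_frac > 0:
            sev_field = _smooth_field((ny, nx), cell_size, 300.0, rng)
            vals = sev_field[foot]
            cut = np.quantile(vals, 1.0 - spec.severity_frac)
            mask[foot] = (sev_field[foot] >= cut).astype(np.int8)
        fires.append((spec, mask))
    return Landscape(cell_size, (0.0, 0.0), elevation, seral, fires)


# ---------------------------------------------------------------------------
# Survey design


def hex_lattice(extent, margin=2600.0):
    """Pointy-top hexagonal lattice of 400-ha cell centers inside the extent."""
    xs, ys = [], []
    row = 0
    y = margin
    vstep = 1.5 * HEX_CIRCUMRADIUS
    while y <= extent[1] - margin:
        x = margin + (HEX_SPACING / 2 if row % 2 else 0.0)
        while x <= extent[0] - margin:
            xs.append(x)
            ys.append(y)
            x += HEX_SPACING
        y += vstep
        row += 1
    return np.column_stack([xs, ys])


def simulate_survey(
    landscape: Landscape,
    n_hex=60,
    seasons=DEFAULT_SEASONS,
    deployment_plan=None,
    seed=0,
) -> SurveyDesign:
    """Sample non-contiguous hexagons, place 2 ARUs >=500 m apart in each,
    and lay out per-season deployment schedules.

    ``deployment_plan`` maps season -> "continuous" (one 35-day interval,
    start staggered across units over the first 7 weeks), "pulsed" (three
    1-week deployments separated by 14-day gaps), or an explicit list of
    (offset_days, length_days).
    """
    if n_hex < 1:
        raise ValueError("n_hex must be >= 1")
    rng = default_rng(seed)
    centers = hex_lattice(landscape.extent)
    order = rng.permutation(len(centers))
    chosen = []
    adj = 1.1 * HEX_SPACING
    for idx in order:
        c = centers[idx]
        if all((c[0] - d[0]) ** 2 + (c[1] - d[1]) ** 2 >= adj**2 for d in chosen):
            chosen.append(c)
        if len(chosen) == n_hex:
            break
    if len(chosen) < n_hex:
        raise ValueError(
            f"cannot place {n_hex} non-contiguous hexagons in this extent "
            f"(placed {len(chosen)})"
        )
    hexes = pd.DataFrame(
        {"hexagon": [f"H{i:03d}" for i in range(n_hex)],
         "x": [c[0] for c in chosen], "y": [c[1] for c in chosen]}
    )

    aru_rows = []
    for _, h in hexes.iterrows():
        theta = rng.uniform(0, 2 * np.pi)
        for j, sign in enumerate((1, -1)):
            d = rng.uniform(300.0, 480.0)  # inside the ~1075-m inradius
            aru_rows.append({
                "aru_id": f"{h.hexagon}_{'AB'[j]}",
                "hexagon": h.hexagon,
                "x": h.x + sign * d * np.cos(theta),
                "y": h.y + sign * d * np.sin(theta),
            })
    arus = pd.DataFrame(aru_rows)

    plan = dict(deployment_plan or {})
    for season in seasons:
        plan.setdefault(season, "pulsed" if season == min(seasons) else "continuous")

    dep_rows = []
    for season in seasons:
        p = plan[season]
        for i, aru in enumerate(arus["aru_id"]):
            if p == "continuous":
                intervals = [(7 * (i % 7), 35)]
            elif p == "pulsed":
                intervals = [(0, 7), (21, 7), (42, 7)]
            elif isinstance(p, (list, tuple)):
                intervals = list(p)
            else:
                raise ValueError(f"unknown deployment plan {p!r}")
            s0 = season_start(season)
            for off, length in intervals:
                dep_rows.append({
                    "aru_id": aru, "season": season,
                    "start": s0 + pd.Timedelta(days=off),
                    "end": s0 + pd.Timedelta(days=off + length),
                })
    deployments = pd.DataFrame(dep_rows)
    return SurveyDesign(hexes, arus, list(seasons), deployments)


# ---------------------------------------------------------------------------
# Covariate extraction shared by the generator and the pipeline


def site_table(
    landscape: Landscape,
    design: SurveyDesign,
    species: str = "flammulated",
    level: str = "aru",
    removals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Static and season-varying covariates for every unit-season row."""
    buf_r = cov.buffer_radius(cov.BUFFER_AREAS_HA[species])
    inv_r = cov.buffer_radius(cov.BUFFER_AREAS_HA["invader"])
    if level == "aru":
        units = design.arus.rename(columns={"aru_id": "unit"})[["unit", "hexagon", "x", "y"]]
    else:
        units = design.hexagons.rename(columns={"hexagon": "unit"}).assign(hexagon=lambda d: d.unit)
        units = units[["unit", "hexagon", "x", "y"]]

    stat = []
    for _, u in units.iterrows():
        pt = (u.x, u.y)
        rug = cov.ruggedness(landscape.elevation, landscape.cell_size, pt, landscape.origin)
        col = int(u.x / landscape.cell_size)
        row = int(u.y / landscape.cell_size)
        elev = float(landscape.elevation[row, col])
        ser = cov.seral_fraction(landscape.seral, landscape.cell_size, landscape.origin, pt, buf_r)
        removal_year = None
        if removals is not None and len(removals):
            hit = [
                r for _, r in removals.iterrows()
                if np.hypot(r.x - u.x, r.y - u.y) < buf_r + inv_r
            ]
            if hit:
                removal_year = int(min(r.year for r in hit))
        stat.append({**u.to_dict(), "ruggedness": rug, "elevation": elev,
                     "seral_frac": ser, "removal_year": removal_year})
    stat = pd.DataFrame(stat)

    rows = []
    for _, u in stat.iterrows():
        # One fire drives the time-since coding: the one contributing the
        # largest severe fraction to this unit's buffer.
        best = (None, 0.0)
        for spec, mask in landscape.fires:
            _, frac = cov.severe_fraction(
                mask, landscape.cell_size, landscape.origin, (u.x, u.y), buf_r,
                season=spec.year + 1, fire_year=spec.year,
            )
            if frac > best[1]:
                best = (spec.year, frac)
        fire_year, frac = best
        for season in design.seasons:
            t = cov.time_since_codings(
                season,
                fire_year,
                u.removal_year if u.removal_year is not None and not pd.isna(u.removal_year) else None,
                frac if fire_year is not None and season > fire_year else 0.0,
            )
            rows.append({
                "unit": u.unit, "hexagon": u.hexagon, "season": season,
                "ruggedness": u.ruggedness, "elevation": u.elevation,
                "seral_frac": u.seral_frac, "removal_year": u.removal_year, **t,
            })
    return pd.DataFrame(rows)


def sample_removals(landscape, design, truth: TruthParams, rng) -> pd.DataFrame:
    """Removal locations near hexagon centers, preferentially in high-seral,
    low-ruggedness cells (the invader's niche), or uniformly."""
    hx = design.hexagons
    feats = []
    for _, h in hx.iterrows():
        ser = cov.seral_fraction(landscape.seral, landscape.cell_size, landscape.origin,
                                 (h.x, h.y), HEX_CIRCUMRADIUS)
        rug = cov.ruggedness(landscape.elevation, landscape.cell_size, (h.x, h.y), landscape.origin)
        feats.append((ser, rug))
    feats = np.array(feats)
    n = min(truth.n_removals, len(hx))
    if truth.removal_placement == "uniform":
        probs = np.ones(len(hx)) / len(hx)
    else:
        rug_sd = feats[:, 1].std() + 1e-9
        score = 3.0 * feats[:, 0] - (feats[:, 1] - feats[:, 1].mean()) / rug_sd
        probs = np.exp(score - score.max())
        probs /= probs.sum()
    pick = rng.choice(len(hx), size=n, replace=False, p=probs)
    return pd.DataFrame({
        "removal_id": [f"R{i:02d}" for i in range(n)],
        "x": hx.iloc[pick].x.values + rng.uniform(-300, 300, n),
        "y": hx.iloc[pick].y.values + rng.uniform(-300, 300, n),
        "year": truth.removal_year,
    })


# ---------------------------------------------------------------------------
# Detection histories


def _weekly_effort(design: SurveyDesign) -> pd.DataFrame:
    """Recorded hours per ARU-season-period (long form)."""
    from .encounters import _effort_hours

    rows = []
    for (aru, season), grp in design.deployments.groupby(["aru_id", "season"]):
        e = _effort_hours(grp, season)
        for k in range(N_PERIODS):
            rows.append({"aru_id": aru, "season": season, "period": k + 1, "hours": e[k]})
    return pd.DataFrame(rows)


def _event_time(rng, deploy: pd.DataFrame, season: int, period: int):
    """A random nocturnal hourly timestamp within the unit's recording
    overlap with the given weekly bin (None if no nocturnal overlap)."""
    w0, w1 = period_windows(season)[period - 1]
    hours = []
    for _, d in deploy.iterrows():
        lo = max(pd.Timestamp(d.start), w0)
        hi = min(pd.Timestamp(d.end), w1)
        t = lo.ceil("h")
        while t < hi:
            if t.hour >= 20 or t.hour < 8:
                hours.append(t)
            t += pd.Timedelta(hours=1)
    if not hours:
        return None
    return hours[int(rng.integers(len(hours)))] + pd.Timedelta(minutes=int(rng.integers(60)))


def simulate_detections(
    design: SurveyDesign,
    landscape: Landscape,
    truth: TruthParams,
    model_id: str,
    species: str = "flammulated",
    level: str = "aru",
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate detection events for the focal species and the invader.

    Latent occupancy z is drawn once per unit-season from the stated model
    equation (with year and site random effects); weekly detections are
    Bernoulli(z * p) with p from the five-predictor logit model, confined to
    weeks with recording effort. Returns the event table and a truth dict
    (psi, z, p, random effects, covariates) for recovery testing.
    """
    from .occupancy import MODEL_COLUMNS

    if model_id not in MODEL_COLUMNS:
        raise ValueError(f"unknown model_id {model_id!r}")
    rng = default_rng(truth.seed if seed is None else seed)

    removals = sample_removals(landscape, design, truth, rng)
    covs = site_table(landscape, design, species=species, level=level, removals=removals)
    effort = _weekly_effort(design)
    eff_lut = {(r.aru_id, r.season, r.period): r.hours for r in effort.itertuples()}
    dep_lut = {k: g for k, g in design.deployments.groupby(["aru_id", "season"])}

    # --- invader occupancy and detections (hexagon scale) ---
    hex_covs = site_table(landscape, design, species="invader", level="hexagon",
                          removals=removals)
    hx = hex_covs.drop_duplicates("unit").set_index("unit")
    el_s, _, _ = cov.standardize(hx.elevation)
    ru_s, _, _ = cov.standardize(hx.ruggedness)
    b0, bel, bru, bser = truth.invader_beta
    inv_rows, inv_events = [], []
    arus_by_hex = {h: g["aru_id"].tolist() for h, g in design.arus.groupby("hexagon")}
    for i, (hname, row) in enumerate(hx.iterrows()):
        eta0 = b0 + bel * el_s[i] + bru * ru_s[i] + bser * row.seral_frac
        removed = row.removal_year is not None and not pd.isna(row.removal_year)
        for season in design.seasons:
            eta = eta0
            if removed and season > truth.removal_year:
                eta += truth.invader_post_removal_drop
            z = int(rng.random() < expit(eta))
            detected = 0
            if z:
                for k in range(1, N_PERIODS + 1):
                    live = [a for a in arus_by_hex[hname]
                            if eff_lut.get((a, season, k), 0.0) > 0]
                    if live and rng.random() < truth.invader_weekly_p:
                        aru = live[int(rng.integers(len(live)))]
                        ts = _event_time(rng, dep_lut[(aru, season)], season, k)
                        if ts is not None:
                            inv_events.append({"aru_id": aru, "timestamp": ts,
                                               "species": "barred_owl",
                                               "score": float(rng.beta(5, 1.5))})
                            detected = 1
            inv_rows.append({"hexagon": hname, "season": season, "z": z, "invader": detected})
    inv_df = pd.DataFrame(inv_rows)
    invader_flag = inv_df.set_index(["hexagon", "season"])["invader"]

    # --- focal species ---
    beta = np.asarray(truth.occupancy_beta[model_id], dtype=float)
    cols = MODEL_COLUMNS[model_id]
    X = np.column_stack([np.ones(len(covs))] + [covs[c].to_numpy(float) for c in cols])
    units = covs["unit"].unique()
    u_site = dict(zip(units, rng.normal(0.0, truth.sigma_site, len(units))))
    u_year = dict(zip(design.seasons, rng.normal(0.0, truth.sigma_year, len(design.seasons))))
    eta_psi = X @ beta + covs["unit"].map(u_site).values + covs["season"].map(u_year).values
    psi = expit(eta_psi)
    z = (rng.random(len(psi)) < psi).astype(int)
    covs = covs.assign(psi=psi, z=z)

    # detection design pieces
    rug_s, _, _ = cov.standardize(covs.drop_duplicates("unit")["ruggedness"])
    rug_map = dict(zip(covs.drop_duplicates("unit")["unit"], rug_s))
    date_mid = np.arange(1, N_PERIODS + 1) * 7.0 - 3.5
    date_s = (date_mid - date_mid.mean()) / date_mid.std()
    eh = effort.copy()
    pos = eh["hours"] > 0
    h_mean, h_sd = eh.loc[pos, "hours"].mean(), eh.loc[pos, "hours"].std() or 1.0

    events = []
    p_record = []
    unit_arus = {u: ([u] if level == "aru" else arus_by_hex[u]) for u in units}
    for _, r in covs.iterrows():
        flag = int(invader_flag.get((r.hexagon, r.season), 0))
        for k in range(1, N_PERIODS + 1):
            unit_hours = {a: eff_lut.get((a, r.season, k), 0.0) for a in unit_arus[r.unit]}
            hours = sum(unit_hours.values())
            if hours <= 0:
                continue
            eta_p = (
                truth.det_intercept
                + truth.det_date * date_s[k - 1]
                + truth.det_year.get(r.season, 0.0)
                + truth.det_ruggedness * rug_map[r.unit]
                + truth.det_hours * (hours - h_mean) / h_sd
                + truth.det_invader * flag
            )
            if truth.extra_p_sd > 0:
                eta_p += rng.normal(0.0, truth.extra_p_sd)
            p = expit(eta_p)
            p_record.append({"unit": r.unit, "season": r.season, "period": k, "p": p})
            if r.z and rng.random() < p:
                live = [a for a, h in unit_hours.items() if h > 0]
                aru = live[int(rng.integers(len(live)))]
                ts = _event_time(rng, dep_lut[(aru, r.season)], r.season, k)
                if ts is not None:
                    events.append({"aru_id": aru, "timestamp": ts, "species": species,
                                   "score": float(rng.beta(5, 1.5))})

    detections = pd.DataFrame(events + inv_events)
    if len(detections):
        detections = detections.sort_values("timestamp").reset_index(drop=True)
    else:
        detections = pd.DataFrame(columns=["aru_id", "timestamp", "species", "score"])
    truth_info = {
        "covariates": covs,
        "psi": psi,
        "z": z,
        "p": pd.DataFrame(p_record),
        "u_site": u_site,
        "u_year": u_year,
        "removals": removals,
        "invader": inv_df,
    }
    return detections, truth_info


def simulate_encounter_data(
    design: SurveyDesign,
    landscape: Landscape,
    truth: TruthParams,
    model_id: str,
    species: str = "flammulated",
    level: str = "aru",
    seed: int | None = None,
    covs: pd.DataFrame | None = None,
    effort: pd.DataFrame | None = None,
):
    """Fast generative path: draw latent occupancy and the weekly 0/1
    matrices directly, skipping event timestamps.

    Statistically identical to :func:`simulate_detections` at the level of
    encounter histories; used for replicate studies (parameter recovery,
    coverage) where only the site-by-week matrices matter. ``covs`` and
    ``effort`` may be precomputed once and reused across replicates.
    """
    from .encounters import EncounterHistory
    from .occupancy import MODEL_COLUMNS

    if model_id not in MODEL_COLUMNS:
        raise ValueError(f"unknown model_id {model_id!r}")
    rng = default_rng(truth.seed if seed is None else seed)
    if covs is None:
        removals = sample_removals(landscape, design, truth, rng)
        covs = site_table(landscape, design, species=species, level=level,
                          removals=removals)
    covs = covs.copy()
    effort = _weekly_effort(design) if effort is None else effort

    # invader presence per hexagon-season from its occurrence model, thinned
    # by the chance of >=1 weekly acoustic detection while units recorded
    hexes = design.hexagons
    el_s, _, _ = cov.standardize([
        landscape.elevation[int(h.y / landscape.cell_size), int(h.x / landscape.cell_size)]
        for _, h in hexes.iterrows()])
    ru = [cov.ruggedness(landscape.elevation, landscape.cell_size, (h.x, h.y),
                         landscape.origin) for _, h in hexes.iterrows()]
    ru_s, _, _ = cov.standardize(ru)
    ser = [cov.seral_fraction(landscape.seral, landscape.cell_size, landscape.origin,
                              (h.x, h.y), HEX_CIRCUMRADIUS) for _, h in hexes.iterrows()]
    b0, bel, bru, bser = truth.invader_beta
    removal_year_by_hex = covs.groupby("hexagon")["removal_year"].first() \
        if "removal_year" in covs else pd.Series(dtype=float)
    arus_by_hex = {h: g["aru_id"].tolist() for h, g in design.arus.groupby("hexagon")}
    eff_lut = {(r.aru_id, r.season, r.period): r.hours for r in effort.itertuples()}
    flags = {}
    for i, (_, h) in enumerate(hexes.iterrows()):
        eta0 = b0 + bel * el_s[i] + bru * ru_s[i] + bser * ser[i]
        r_year = removal_year_by_hex.get(h.hexagon)
        for season in design.seasons:
            eta = eta0
            if r_year is not None and not pd.isna(r_year) and season > truth.removal_year:
                eta += truth.invader_post_removal_drop
            z = rng.random() < expit(eta)
            weeks_live = sum(
                any(eff_lut.get((a, season, k), 0.0) > 0 for a in arus_by_hex[h.hexagon])
                for k in range(1, N_PERIODS + 1))
            det_p = -np.expm1(weeks_live * np.log1p(-truth.invader_weekly_p)) if weeks_live else 0.0
            flags[(h.hexagon, season)] = int(z and rng.random() < det_p)
    covs["invader"] = [flags[(r.hexagon, r.season)] for r in covs.itertuples()]

    beta = np.asarray(truth.occupancy_beta[model_id], dtype=float)
    X = np.column_stack([np.ones(len(covs))]
                        + [covs[c].to_numpy(float) for c in MODEL_COLUMNS[model_id]])
    units = covs["unit"].unique()
    u_site = dict(zip(units, rng.normal(0.0, truth.sigma_site, len(units))))
    u_year = dict(zip(design.seasons, rng.normal(0.0, truth.sigma_year, len(design.seasons))))
    eta_psi = X @ beta + covs["unit"].map(u_site).values + covs["season"].map(u_year).values
    psi = expit(eta_psi)
    z = (rng.random(len(psi)) < psi).astype(int)

    # effort matrix per unit-season row
    E = np.zeros((len(covs), N_PERIODS))
    for i, r in enumerate(covs.itertuples()):
        arus = [r.unit] if level == "aru" else arus_by_hex[r.unit]
        for k in range(1, N_PERIODS + 1):
            E[i, k - 1] = sum(eff_lut.get((a, r.season, k), 0.0) for a in arus)

    rug_units = covs.drop_duplicates("unit")
    rug_s, _, _ = cov.standardize(rug_units["ruggedness"])
    rug_map = dict(zip(rug_units["unit"], rug_s))
    date_mid = np.arange(1, N_PERIODS + 1) * 7.0 - 3.5
    date_s = (date_mid - date_mid.mean()) / date_mid.std()
    pos = E > 0
    h_mean = E[pos].mean()
    h_sd = E[pos].std() or 1.0
    eta_p = (
        truth.det_intercept
        + truth.det_date * date_s[None, :]
        + covs["season"].map(truth.det_year).fillna(0.0).to_numpy()[:, None]
        + np.array([rug_map[u] for u in covs["unit"]])[:, None] * truth.det_ruggedness
        + truth.det_hours * (E - h_mean) / h_sd
        + truth.det_invader * covs["invader"].to_numpy()[:, None]
    )
    if truth.extra_p_sd > 0:
        eta_p = eta_p + rng.normal(0.0, truth.extra_p_sd, eta_p.shape)
    p = expit(eta_p)
    y = np.where(pos, ((rng.random(p.shape) < p) & (z[:, None] == 1)).astype(float), np.nan)

    hist_df = pd.DataFrame({
        "unit": covs["unit"], "hexagon": covs["hexagon"], "season": covs["season"],
        **{f"y{k + 1}": y[:, k] for k in range(N_PERIODS)},
        **{f"e{k + 1}": E[:, k] for k in range(N_PERIODS)},
    })
    hist = EncounterHistory(df=hist_df.reset_index(drop=True), level=level, species=species)
    truth_info = {"psi": psi, "z": z, "p": p, "u_site": u_site, "u_year": u_year}
    return hist, covs, truth_info


def simulate_simple_history(psi, p, n_sites, n_periods, seed=0):
    """Site-by-period 0/1 history from constant psi and p (no covariates)."""
    rng = default_rng(seed)
    z = rng.random(n_sites) < psi
    y = (rng.random((n_sites, n_periods)) < p) & z[:, None]
    return y.astype(float), z.astype(int)


# ---------------------------------------------------------------------------
# Classifier score streams


def simulate_scores(
    profile: SpeciesScoreProfile,
    n_hours: int = 3000,
    seed: int = 0,
    aru_id: str = "SIM",
    start: str = "2021-05-07 20:00",
) -> list[HourSample]:
    """Hourly prediction-score samples with planted true and false positives.

    The hour label is 1 iff at least one true call was planted in the hour;
    all prediction scores (true and false, any magnitude) are pooled into the
    hour's score list, as a classifier would emit them.
    """
    if profile.true_rate < 0 or profile.fp_rate < 0:
        raise ValueError("rates must be non-negative")
    rng = default_rng(seed)
    t0 = pd.Timestamp(start)
    out = []
    n_true = rng.poisson(profile.true_rate, n_hours)
    n_fp = rng.poisson(profile.fp_rate, n_hours)
    for i in range(n_hours):
        tp = rng.beta(*profile.tp_beta, n_true[i])
        fp = rng.beta(*profile.fp_beta, n_fp[i])
        out.append(HourSample(
            aru_id=aru_id,
            hour_start=str(t0 + pd.Timedelta(hours=i)),
            label=int(n_true[i] > 0),
            scores=np.concatenate([tp, fp]),
        ))
    return out


def validation_sample(streams: list[HourSample], min_score: float = 0.1,
                      n: int | None = None, seed: int = 0) -> list[HourSample]:
    """Hours containing >=1 prediction above ``min_score`` (the manual-review
    candidate pool), optionally subsampled to n hours."""
    pool = [s for s in streams if s.scores.size and s.scores.max() >= min_score]
    if n is not None and len(pool) > n:
        rng = default_rng(seed)
        pool = [pool[i] for i in rng.choice(len(pool), n, replace=False)]
    return pool


def simulate_fp_weeks(
    profile: SpeciesScoreProfile,
    threshold: float,
    n_weeks: int = 1000,
    hours_per_week: int = 84,
    seed: int = 0,
) -> float:
    """Fraction of simulated weeks containing >=1 false prediction with score
    >= threshold, simulating the false-positive score process directly."""
    rng = default_rng(seed)
    counts = rng.poisson(profile.fp_rate * hours_per_week, n_weeks)
    total = int(counts.sum())
    scores = rng.beta(*profile.fp_beta, total)
    flagged = scores >= threshold
    idx = np.repeat(np.arange(n_weeks), counts)
    hit = np.zeros(n_weeks, dtype=bool)
    np.logical_or.at(hit, idx, flagged)
    return float(hit.mean())


# ---------------------------------------------------------------------------
# Writers (plain-text artifacts)


def write_grid(path: Path, name: str, grid: np.ndarray, cell_size: float, origin):
    header = {"name": name, "shape": list(grid.shape), "cell_size": cell_size,
              "origin": list(origin)}
    (path / f"{name}.json").write_text(json.dumps(header))
    np.savetxt(path / f"{name}.txt", grid, fmt="%.2f" if grid.dtype.kind == "f" else "%d")


def write_outputs(outdir, landscape: Landscape, design: SurveyDesign,
                  detections: pd.DataFrame, truth_info: dict | None = None):
    """Write detections.csv, deployments.csv, sites.csv, grids, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    detections.to_csv(outdir / "detections.csv", index=False)
    design.deployments.to_csv(outdir / "deployments.csv", index=False)
    design.arus.rename(columns={"aru_id": "aru_id"}).to_csv(outdir / "sites.csv", index=False)
    design.hexagons.to_csv(outdir / "hexagons.csv", index=False)
    write_grid(outdir, "elevation", landscape.elevation, landscape.cell_size, landscape.origin)
    write_grid(outdir, "seral", landscape.seral, landscape.cell_size, landscape.origin)
    for i, (spec, mask) in enumerate(landscape.fires):
        write_grid(outdir, f"burn_{spec.year}_{i}", mask, landscape.cell_size, landscape.origin)
    if truth_info is not None:
        truth_info["removals"].to_csv(outdir / "removals.csv", index=False)
        payload = {
            "u_site": truth_info["u_site"], "u_year": truth_info["u_year"],
            "psi": list(map(float, truth_info["psi"])),
            "z": list(map(int, truth_info["z"])),
        }
        (outdir / "truth.json").write_text(json.dumps(payload, default=float))
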