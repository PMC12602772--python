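"""Weekly encounter histories from detection events and deployment records.

The survey season is divided into 11 one-week secondary sampling periods,
half-open bins starting May 7 00:00 (so the season spans 77 days and ends at
July 23 00:00 exclusive). Only nocturnal events (20:00-08:00) count as
surveys. A period in which a unit recorded zero hours is missing (NaN); a
partially recorded period keeps its data, with the recorded hours carried as
a detection-effort covariate.

Histories can be built at ARU level (small, quiet species: the two units in a
hexagon are independent sites) or at hexagon level (large, loud species: the
two units are pooled — detections unioned, effort summed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["N_PERIODS", "EncounterHistory", "assign_period", "period_windows",
           "build_history", "invader_covariate", "is_nocturnal"]

N_PERIODS = 11
SEASON_START = (5, 7)  # May 7
NIGHT_START, NIGHT_END = 20, 8  # 20:00 .. 08:00


@dataclass
class EncounterHistory:
    """Site-by-period detection and effort matrices, stacked over seasons.

    ``df`` has one row per unit-season with columns ``y1..y11`` (0/1/NaN),
    ``e1..e11`` (hours recorded), plus ``unit``, ``hexagon``, ``season``.
    """

    df: pd.DataFrame
    level: str
    species: str

    @property
    def y(self) -> np.ndarray:
        return self.df[[f"y{k}" for k in range(1, N_PERIODS + 1)]].to_numpy(float)

    @property
    def effort(self) -> np.ndarray:
        return self.df[[f"e{k}" for k in range(1, N_PERIODS + 1)]].to_numpy(float)

    def to_csv(self, path):
        self.df.to_csv(path, index=False)


def season_start(season: int) -> pd.Timestamp:
    return pd.Timestamp(season, *SEASON_START)


def period_windows(season: int):
    """List of (start, end) timestamps for the 11 half-open weekly bins."""
    s0 = season_start(season)
    return [(s0 + pd.Timedelta(days=7 * k), s0 + pd.Timedelta(days=7 * (k + 1)))
            for k in range(N_PERIODS)]


def assign_period(timestamp, season: int):
    """1-based secondary period index for a timestamp, or None outside the
    season window [May 7, +77 days)."""
    ts = pd.Timestamp(timestamp)
    delta = (ts - season_start(season)) / pd.Timedelta(days=7)
    if delta < 0 or delta >= N_PERIODS:
        return None
    return int(delta) + 1


def is_nocturnal(timestamp) -> bool:
    h = pd.Timestamp(timestamp).hour
    return h >= NIGHT_START or h < NIGHT_END


def _effort_hours(deploy_df: pd.DataFrame, season: int) -> np.ndarray:
    """Hours of recording overlap with each weekly bin for one unit-season."""
    e = np.zeros(N_PERIODS)
    windows = period_windows(season)
    for _, row in deploy_df.iterrows():
        start, end = pd.Timestamp(row["start"]), pd.Timestamp(row["end"])
        for k, (w0, w1) in enumerate(windows):
            lo, hi = max(start, w0), min(end, w1)
            if hi > lo:
                e[k] += (hi - lo) / pd.Timedelta(hours=1)
    return e


def build_history(
    detections: pd.DataFrame,
    deployments: pd.DataFrame,
    sites: pd.DataFrame,
    species: str,
    level: str = "aru",
    effort_rule: str = "sum",
) -> EncounterHistory:
    """Build the stacked weekly encounter history for one species.

    Parameters
    ----------
    detections : columns ``aru_id``, ``timestamp``, ``species``.
    deployments : columns ``aru_id``, ``season``, ``start``, ``end``.
    sites : columns ``aru_id``, ``hexagon``.
    level : ``"aru"`` or ``"hexagon"``.
    effort_rule : hexagon-level pooling of the two units' hours
        (``"sum"``, bounded 0-336, or ``"max"``).
    """
    if level not in ("aru", "hexagon"):
        raise ValueError(f"unknown level {level!r}")
    known = set(sites["aru_id"])
    det = detections[detections["species"] == species].copy()
    unknown = set(det["aru_id"]) - known
    if unknown:
        raise ValueError(f"detection events reference unknown ARUs: {sorted(unknown)[:5]}")
    det["timestamp"] = pd.to_datetime(det["timestamp"])
    det = det[det["timestamp"].map(is_nocturnal).astype(bool)]

    hex_of = dict(zip(sites["aru_id"], sites["hexagon"]))
    seasons = sorted(deployments["season"].unique())
    rows = []
    for season in seasons:
        dep = deployments[deployments["season"] == season]
        dsea = det[det["timestamp"].dt.year == season]
        for aru, dgrp in dep.groupby("aru_id"):
            e = _effort_hours(dgrp, season)
            y = np.zeros(N_PERIODS)
            for ts in dsea.loc[dsea["aru_id"] == aru, "timestamp"]:
                k = assign_period(ts, season)
                if k is None:
                    continue
                if e[k - 1] <= 0:
                    raise ValueError(
                        f"detection at {ts} for {aru} falls in a period with zero effort"
                    )
                y[k - 1] = 1
            y = np.where(e > 0, y, np.nan)
            rows.append({"unit": aru, "hexagon": hex_of[aru], "season": season,
                         **{f"y{k + 1}": y[k] for k in range(N_PERIODS)},
                         **{f"e{k + 1}": e[k] for k in range(N_PERIODS)}})
    df = pd.DataFrame(rows)

    if level == "hexagon":
        ycols = [f"y{k}" for k in range(1, N_PERIODS + 1)]
        ecols = [f"e{k}" for k in range(1, N_PERIODS + 1)]
        agg = {}
        for c in ycols:
            agg[c] = "max"  # union of the two units; NaN only if both missing
        for c in ecols:
            agg[c] = effort_rule if effort_rule in ("sum", "max") else "sum"
        df = df.groupby(["hexagon", "season"], as_index=False).agg(agg)
        df["unit"] = df["hexagon"]
        # Pooled detection in a zero-effort period cannot arise: per-unit rows
        # are NaN-masked wherever their own effort is zero.
        df = df[["unit", "hexagon", "season"] + ycols + ecols]
    return EncounterHistory(df=df.reset_index(drop=True), level=level, species=species)


def invader_covariate(
    invader_history: EncounterHistory | pd.DataFrame,
) -> pd.DataFrame:
    """Hexagon-season binary flag: 1 if the invading species was detected at
    least once that year at either unit of the hexagon."""
    df = invader_history.df if isinstance(invader_history, EncounterHistory) else invader_history
    ycols = [c for c in df.columns if c.startswith("y") and c[1:].isdigit()]
    detected = (df[ycols] == 1).any(axis=1).astype(int)
    out = (
        df.assign(invader=detected)
        .groupby(["hexagon", "season"], as_index=False)["invader"]
        .max()
    )
    return out
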