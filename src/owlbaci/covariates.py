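"""Site-year environmental predictors for the occupancy models.

All geometry is planar, in meters. Home ranges are circular buffers whose
areas are species-specific (flammulated owl 50 ha, pygmy owl 300 ha, great
horned owl 700 ha around the hexagon center, invading barred owl 2004 ha).
Raster layers are plain 2-D arrays with a cell size and an origin; cells are
attributed to a buffer by cell-center inclusion.

Time-since codings implement the BACI design:

* ``burn`` — indicator that any high-severity fire fell in the buffer.
* ``allpostburn`` — the high-severity fraction, for every season after the
  fire (zero before).
* ``burn1/2/3`` — the same fraction, but only in the season exactly 1, 2, or
  3 years post-fire.
* ``site_type`` — home-range buffer overlaps a removal buffer.
* ``allpostlethal`` and ``lethal1/2/3plus`` — removal-site indicators for any
  post-removal season and for exact year offsets (3plus = three or more).
* Interaction indicators mark removal sites subsequently burned (binary, even
  where the marginal fire terms are fraction-valued).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "BUFFER_AREAS_HA",
    "buffer_radius",
    "ruggedness",
    "severe_fraction",
    "time_since_codings",
    "removal_overlap",
    "seral_fraction",
    "standardize",
    "predictor_correlations",
]

#: Home-range buffer areas (ha) used throughout the study.
BUFFER_AREAS_HA = {
    "flammulated": 50.0,
    "pygmy": 300.0,
    "great_horned": 700.0,
    "invader": 2004.0,
}


def buffer_radius(area_ha: float) -> float:
    """Radius (m) of a circle with the given area in hectares."""
    if area_ha <= 0:
        raise ValueError("buffer area must be positive")
    return float(np.sqrt(area_ha * 1e4 / np.pi))


def _window(shape, cell_size, origin, center, radius):
    """(row slice, col slice, boolean mask) of cells whose centers fall
    within radius of center, restricted to the circle's bounding window."""
    nrow, ncol = shape
    x0, y0 = origin
    c0 = max(int(np.floor((center[0] - radius - x0) / cell_size)), 0)
    c1 = min(int(np.ceil((center[0] + radius - x0) / cell_size)) + 1, ncol)
    r0 = max(int(np.floor((center[1] - radius - y0) / cell_size)), 0)
    r1 = min(int(np.ceil((center[1] + radius - y0) / cell_size)) + 1, nrow)
    if r0 >= r1 or c0 >= c1:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0), dtype=bool)
    xs = x0 + (np.arange(c0, c1) + 0.5) * cell_size
    ys = y0 + (np.arange(r0, r1) + 0.5) * cell_size
    dx = xs[None, :] - center[0]
    dy = ys[:, None] - center[1]
    mask = dx * dx + dy * dy <= radius * radius
    return slice(r0, r1), slice(c0, c1), mask


def _cells_within(shape, cell_size, origin, center, radius):
    """Full-grid boolean mask of cells whose centers lie within the circle."""
    rs, cs, sub = _window(shape, cell_size, origin, center, radius)
    mask = np.zeros(shape, dtype=bool)
    mask[rs, cs] = sub
    return mask


def ruggedness(elevation, cell_size, point, origin=(0.0, 0.0), radius=390.0):
    """Terrain ruggedness (m) around a point.

    For every raster cell whose center lies within ``radius`` of the point,
    compute the mean absolute elevation difference to its eight neighbors;
    return the mean over those cells. Cells on the raster edge have no full
    neighborhood, so a buffer reaching the edge is an error rather than an
    extrapolation.
    """
    elev = np.asarray(elevation, dtype=float)
    rs, cs, mask = _window(elev.shape, cell_size, origin, point, radius)
    if not mask.any():
        raise ValueError("ruggedness buffer contains no raster cells")
    rows, cols = np.nonzero(mask)
    rows, cols = rows + rs.start, cols + cs.start
    if rows.min() < 1 or cols.min() < 1 or rows.max() >= elev.shape[0] - 1 or cols.max() >= elev.shape[1] - 1:
        raise ValueError("ruggedness buffer exceeds the elevation grid")
    # neighbor sums only over the buffer's bounding window (plus a 1-cell rim)
    w = elev[rows.min() - 1 : rows.max() + 2, cols.min() - 1 : cols.max() + 2]
    core = w[1:-1, 1:-1]
    acc = np.zeros_like(core)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            acc += np.abs(w[1 + di : w.shape[0] - 1 + di, 1 + dj : w.shape[1] - 1 + dj] - core)
    per_cell = acc / 8.0
    return float(per_cell[rows - rows.min(), cols - cols.min()].mean())


def severe_fraction(burn, cell_size, origin, center, radius, season, fire_year):
    """(burn indicator, high-severity fraction) for one site-season.

    Fraction = severely burned cell area within the home-range buffer divided
    by buffer area (cell-center rule); both outputs are zero for seasons at or
    before the fire year (fires here burn in late summer, after the survey
    season of the same calendar year closes).
    """
    if season <= fire_year:
        return 0, 0.0
    burn = np.asarray(burn)
    rs, cs, mask = _window(burn.shape, cell_size, origin, center, radius)
    if not mask.any():
        raise ValueError("buffer contains no raster cells")
    frac = float(burn[rs, cs][mask].mean())
    return int(frac > 0), frac


def seral_fraction(seral, cell_size, origin, center, radius) -> float:
    """Fraction of the buffer in intermediate-to-late seral forest
    (binary layer: QMD >= 25 cm and canopy cover > 40%)."""
    seral = np.asarray(seral)
    rs, cs, mask = _window(seral.shape, cell_size, origin, center, radius)
    if not mask.any():
        raise ValueError("buffer contains no raster cells")
    return float(seral[rs, cs][mask].mean())


def time_since_codings(season, fire_year, removal_year, fraction):
    """All BACI time-offset fields for one site-year row.

    ``fire_year``/``removal_year`` may be None when the site saw no fire /
    no removal. ``fraction`` is the high-severity fraction in the buffer.
    """
    out = {
        "burn": 0,
        "allpostburn": 0.0,
        "burn1": 0.0,
        "burn2": 0.0,
        "burn3": 0.0,
        "site_type": 0,
        "allpostlethal": 0,
        "lethal1": 0,
        "lethal2": 0,
        "lethal3plus": 0,
        "postlethal_x_burnyrs": 0,
        "postlethal_x_burn1": 0,
        "postlethal_x_burn2": 0,
        "postlethal_x_burn3": 0,
    }
    post_fire = fire_year is not None and season > fire_year and fraction > 0
    if post_fire:
        offset = season - fire_year
        out["burn"] = 1
        out["allpostburn"] = float(fraction)
        if offset in (1, 2, 3):
            out[f"burn{offset}"] = float(fraction)
    if removal_year is not None:
        out["site_type"] = 1
        r_off = season - removal_year
        if r_off >= 1:
            out["allpostlethal"] = 1
            if r_off >= 3:
                out["lethal3plus"] = 1
            else:
                out[f"lethal{r_off}"] = 1
    # Interactions: a removal followed by fire, expressed as binary
    # indicators even though the marginal fire terms carry fractions.
    if (
        removal_year is not None
        and fire_year is not None
        and removal_year < fire_year
        and post_fire
    ):
        out["postlethal_x_burnyrs"] = 1
        offset = season - fire_year
        if offset in (1, 2, 3):
            out[f"postlethal_x_burn{offset}"] = 1
    return out


def removal_overlap(site_xy, site_radius, removal_xys, removal_radius) -> int:
    """1 iff the site's home-range circle strictly overlaps any removal
    circle (tangency counts as non-overlap)."""
    removal_xys = np.atleast_2d(np.asarray(removal_xys, dtype=float))
    if removal_xys.size == 0:
        return 0
    d = np.hypot(removal_xys[:, 0] - site_xy[0], removal_xys[:, 1] - site_xy[1])
    return int(np.any(d < site_radius + removal_radius))


def standardize(values):
    """Z-score a vector; returns (standardized, mean, sd). sd=1 if constant."""
    v = np.asarray(values, dtype=float)
    mu = float(np.nanmean(v))
    sd = float(np.nanstd(v))
    if sd == 0 or not np.isfinite(sd):
        sd = 1.0
    return (v - mu) / sd, mu, sd


def predictor_correlations(df: pd.DataFrame, columns, warn_above: float = 0.6):
    """Pairwise Pearson correlations among predictors; warns above 0.6,
    mirroring the collinearity screen used for the occupancy models."""
    corr = df[list(columns)].corr(method="pearson")
    tri = corr.where(np.triu(np.ones_like(corr, dtype=bool), k=1))
    hot = tri.stack()[lambda s: s.abs() > warn_above]
    for (a, b), r in hot.items():
        warnings.warn(f"predictors {a!r} and {b!r} correlate at r={r:.2f}", stacklevel=2)
    return corr
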