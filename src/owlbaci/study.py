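"""Headline figures from the Sierra Nevada owl BACI study, as published.

These constants are *inputs* (printed study-system quantities), kept here so
that derived arithmetic — fold changes, high-severity percentages — is
computed rather than restated. Nothing in the modelling code depends on them.
"""

from __future__ import annotations

#: Invasive barred owl site occupancy before (2018) and after (2020) removals.
INVADER_OCCUPANCY_BEFORE = 0.19
INVADER_OCCUPANCY_AFTER = 0.03

#: Flammulated owl occupancy at removal sites, pre- vs post-removal.
FLAMMULATED_PSI_PRE_REMOVAL = 0.09
FLAMMULATED_PSI_POST_REMOVAL = 0.18

#: Fire footprints: (total burned km^2, high-severity km^2).
FIRES = {
    "north_complex": {"year": 2020, "burned_km2": 1220.0, "severe_km2": 599.0},
    "dixie": {"year": 2021, "burned_km2": 3740.0, "severe_km2": 2090.0},
}


def fold_change(after: float, before: float) -> float:
    """Ratio of two occupancy estimates (e.g. post/pre removal)."""
    if before <= 0:
        raise ValueError("baseline occupancy must be positive")
    return after / before


def percent_high_severity(fire: str) -> float:
    """Percentage of a fire's footprint that burned at high severity."""
    f = FIRES[fire]
    return 100.0 * f["severe_km2"] / f["burned_km2"]
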