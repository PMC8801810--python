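"""Rule-based classification of multi-year grassland disturbance change.

The engine combines, per grassland pixel, the interannual trend of the
disturbance index (DI) and of the greening abundance (GA) — each a
Theil-Sen slope with a Mann-Kendall significance verdict — plus the
pixel's land-cover history, into one of seven change types or "stable":

====================================  =======================================
condition                             class
====================================  =======================================
grassland turned to water             turned_to_water (overrides trends)
DI trend not significant              stable
DI sig., GA sig. rising, DI rising    recovery
DI sig., GA sig. rising, DI falling   greenness_increase
DI sig., GA sig. falling              degradation
DI sig., GA n.s. rising, DI rising    potential_recovery
DI sig., GA n.s. rising, DI falling   potential_greenness_increase
DI sig., GA n.s. falling              potential_degradation
missing/short trend inputs            insufficient_data
====================================  =======================================

A significant DI trend marks the pixel as disturbed; the GA trend then
says whether greenness responded significantly (a realised change) or
only tendentially (a "potential" change).  The recovery-vs-greenness-
increase split uses the DI slope sign: rising DI alongside rising
greenness reads as recovery under ongoing disturbance pressure, falling
DI alongside rising greenness as a greenness increase with relaxing
disturbance.  A GA slope of exactly zero under a significant DI trend is
resolved deterministically (potential_recovery if the DI slope is
negative, else potential_degradation).  The rule table is total: every
input combination maps to exactly one class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CLASS_CODES
from .trend_stats import TrendResult

__all__ = [
    "DISTURBANCE_CODES",
    "DISTURBANCE_NAMES",
    "RuleDecision",
    "classify_pixel",
    "classify_map",
    "detect_water_transition",
    "fraction_table",
]

DISTURBANCE_CODES = {
    "stable": 0,
    "recovery": 1,
    "potential_recovery": 2,
    "degradation": 3,
    "potential_degradation": 4,
    "greenness_increase": 5,
    "potential_greenness_increase": 6,
    "turned_to_water": 7,
    "insufficient_data": 8,
}
DISTURBANCE_NAMES = {v: k for k, v in DISTURBANCE_CODES.items()}

#: The seven change types (everything except stable/insufficient).
CHANGE_TYPES = [
    "recovery",
    "potential_recovery",
    "degradation",
    "potential_degradation",
    "greenness_increase",
    "potential_greenness_increase",
    "turned_to_water",
]


@dataclass(frozen=True)
class RuleDecision:
    """One pixel's classification with the rule that fired."""

    disturbance_class: str
    rule_id: str

    @property
    def code(self) -> int:
        return DISTURBANCE_CODES[self.disturbance_class]


def _decide(
    di_sig: bool,
    di_slope: float,
    ga_sig: bool,
    ga_slope: float,
    turned_to_water: bool,
    inputs_valid: bool,
) -> RuleDecision:
    if turned_to_water:
        return RuleDecision("turned_to_water", "W")
    if not inputs_valid:
        return RuleDecision("insufficient_data", "X")
    if not di_sig:
        return RuleDecision("stable", "S")
    if ga_sig and ga_slope > 0:
        if di_slope >= 0:
            return RuleDecision("recovery", "R1")
        return RuleDecision("greenness_increase", "G1")
    if ga_sig and ga_slope < 0:
        return RuleDecision("degradation", "D1")
    # GA not significant
    if ga_slope > 0:
        if di_slope >= 0:
            return RuleDecision("potential_recovery", "R2")
        return RuleDecision("potential_greenness_increase", "G2")
    if ga_slope < 0:
        return RuleDecision("potential_degradation", "D2")
    # GA slope exactly zero under a significant DI trend
    if di_slope < 0:
        return RuleDecision("potential_recovery", "Z1")
    return RuleDecision("potential_degradation", "Z2")


def classify_pixel(
    di: TrendResult,
    ga: TrendResult,
    turned_to_water: bool = False,
) -> RuleDecision:
    """Apply the decision table to one pixel's DI/GA trend results."""
    inputs_valid = bool(di.valid and ga.valid)
    return _decide(
        di_sig=bool(di.significant),
        di_slope=float(di.sen_slope) if inputs_valid else 0.0,
        ga_sig=bool(ga.significant),
        ga_slope=float(ga.sen_slope) if inputs_valid else 0.0,
        turned_to_water=turned_to_water,
        inputs_valid=inputs_valid,
    )


def detect_water_transition(
    annual_maps: dict[int, np.ndarray],
    baseline_grassland: np.ndarray,
    n_final_years: int = 3,
) -> np.ndarray:
    """True where a baseline-grassland pixel is water in the majority of
    the final ``n_final_years`` annual maps.

    With fewer than ``n_final_years`` maps available the result is all
    False (warned), so a short record never fabricates transitions.
    """
    years = sorted(annual_maps)
    baseline_grassland = np.asarray(baseline_grassland, dtype=bool)
    if len(years) < n_final_years:
        import warnings

        warnings.warn(
            f"only {len(years)} annual maps; water-transition detection needs "
            f">= {n_final_years}, returning no transitions",
            stacklevel=2,
        )
        return np.zeros_like(baseline_grassland)
    final = np.stack([np.asarray(annual_maps[y]) for y in years[-n_final_years:]])
    water_votes = np.sum(final == CLASS_CODES["water"], axis=0)
    majority = water_votes > n_final_years / 2
    return baseline_grassland & majority


def classify_map(
    di_trends: dict,
    ga_trends: dict,
    annual_maps: dict[int, np.ndarray],
    baseline: str = "first_year",
    min_grass_years: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-pixel disturbance classification over the grassland mask.

    ``di_trends``/``ga_trends`` are the raster dicts from
    :func:`amtdr.trend_stats.trend_analysis`.  The grassland mask is the
    set of pixels mapped grassland in the first year (``baseline=
    "first_year"``), or grassland in at least ``min_grass_years`` years
    (``baseline="min_years"``).  Pixels outside the mask get -1.

    Returns the code raster and the fraction table over disturbed
    pixels (see :func:`fraction_table`).
    """
    years = sorted(annual_maps)
    first = np.asarray(annual_maps[years[0]])
    shape = first.shape
    for d in (di_trends, ga_trends):
        if d["sen_slope"].shape != shape:
            raise ValueError("trend rasters and maps must share one grid")
    if baseline == "first_year":
        grass = first == CLASS_CODES["grassland"]
    elif baseline == "min_years":
        if min_grass_years is None:
            raise ValueError("min_grass_years required for baseline='min_years'")
        stack = np.stack([np.asarray(annual_maps[y]) for y in years])
        grass = np.sum(stack == CLASS_CODES["grassland"], axis=0) >= min_grass_years
    else:
        raise ValueError(f"unknown baseline rule {baseline!r}")

    to_water = detect_water_transition(annual_maps, grass)

    di_sig = np.asarray(di_trends["significant"], dtype=bool)
    ga_sig = np.asarray(ga_trends["significant"], dtype=bool)
    di_slope = np.asarray(di_trends["sen_slope"], dtype=float)
    ga_slope = np.asarray(ga_trends["sen_slope"], dtype=float)
    valid = np.asarray(di_trends["valid"], dtype=bool) & np.asarray(
        ga_trends["valid"], dtype=bool
    )

    out = np.full(shape, -1, dtype=np.int16)
    C = DISTURBANCE_CODES
    g = grass
    out[g] = C["stable"]
    out[g & ~valid] = C["insufficient_data"]
    act = g & valid & di_sig
    with np.errstate(invalid="ignore"):
        out[act & ga_sig & (ga_slope > 0) & (di_slope >= 0)] = C["recovery"]
        out[act & ga_sig & (ga_slope > 0) & (di_slope < 0)] = C["greenness_increase"]
        out[act & ga_sig & (ga_slope < 0)] = C["degradation"]
        ns = act & ~ga_sig
        out[ns & (ga_slope > 0) & (di_slope >= 0)] = C["potential_recovery"]
        out[ns & (ga_slope > 0) & (di_slope < 0)] = C["potential_greenness_increase"]
        out[ns & (ga_slope < 0)] = C["potential_degradation"]
        zero = ns & (ga_slope == 0)
        out[zero & (di_slope < 0)] = C["potential_recovery"]
        out[zero & (di_slope >= 0)] = C["potential_degradation"]
    out[g & to_water] = C["turned_to_water"]
    return out, fraction_table(out)


def fraction_table(class_raster: np.ndarray) -> pd.DataFrame:
    """Share of each change type among disturbed pixels (percent).

    Disturbed pixels are those carrying one of the seven change types;
    the fractions sum to 100 up to rounding.  Also reports the disturbed
    share of the grassland mask.
    """
    out = np.asarray(class_raster)
    change_codes = [DISTURBANCE_CODES[name] for name in CHANGE_TYPES]
    disturbed = np.isin(out, change_codes)
    n_disturbed = int(disturbed.sum())
    n_grass = int(np.sum(out >= 0) - np.sum(out == DISTURBANCE_CODES["insufficient_data"]))
    rows = []
    for name in CHANGE_TYPES:
        count = int(np.sum(out == DISTURBANCE_CODES[name]))
        rows.append(
            {
                "change_type": name,
                "pixel_count": count,
                "fraction_of_disturbed_pct": (
                    100.0 * count / n_disturbed if n_disturbed else np.nan
                ),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_disturbed"] = n_disturbed
    df.attrs["n_grassland"] = n_grass
    df.attrs["disturbed_fraction_of_grassland_pct"] = (
        100.0 * n_disturbed / n_grass if n_grass else np.nan
    )
    return df
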