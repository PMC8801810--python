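"""Spectral-temporal indices: NIRv, tasseled-cap components, the
disturbance index (DI) and the greening abundance (GA).

The science in brief
--------------------
* NIRv — the near-infrared reflectance of vegetation — is the product of
  NDVI and NIR reflectance; it tracks the photosynthetic vegetation
  signal and is robust to mixed pixels.
* The tasseled-cap transformation maps the 7 reflectance bands into
  brightness (B), greenness (G) and wetness (W) via fixed linear
  coefficients (MODIS NBAR set, stored in a swappable YAML file).
* DI is computed on *standardized* components: each of B, G, W is
  z-scored against the mean and SD of a vegetation reference set, and

      DI = B_r - (G_r + W_r).

  Disturbance exposes bright soil and removes green, moist canopy, so
  brightness rises while greenness and wetness fall — all three shifts
  push DI up.
* GA summarises the growing-season (May-September) greenness of one
  pixel-year: take the daily NIRv profile over the window, locate the
  dates of its minimum and maximum, and average NIRv over the inclusive
  date span between them (order-agnostic; ties broken by earliest date).

The per-pixel, per-year feature vector used by the land-cover classifier
is {NIRv, DI, TC1, TC2, TC3} x {growing-season max, min, mean} = 15
numbers, with GA carried alongside.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TCCoefficients",
    "StandardizationStats",
    "load_tc_coefficients",
    "compute_ndvi",
    "compute_nirv",
    "compute_tasseled_cap",
    "fit_standardization",
    "standardize_tc",
    "compute_di",
    "compute_ga",
    "GROWING_SEASON",
    "FEATURE_NAMES",
    "features_for_year",
]

#: Day-of-year window of the single May 1 - Sep 30 growing season
#: (365-day calendar, inclusive endpoints).
GROWING_SEASON = (121, 273)

_COMPONENTS = ("brightness", "greenness", "wetness")

#: Column order of the 15-element classifier feature vector.
FEATURE_NAMES = [
    f"{var}_{stat}"
    for var in ("nirv", "di", "tc1", "tc2", "tc3")
    for stat in ("max", "min", "mean")
]


@dataclass(frozen=True)
class TCCoefficients:
    """Tasseled-cap coefficient rows (each length 7) plus provenance."""

    brightness: tuple
    greenness: tuple
    wetness: tuple
    band_order: tuple
    version: str

    @property
    def matrix(self) -> np.ndarray:
        return np.array([self.brightness, self.greenness, self.wetness], dtype=float)


def load_tc_coefficients(path: str | Path | None = None) -> TCCoefficients:
    """Load a tasseled-cap coefficient set (default: packaged MODIS set)."""
    if path is None:
        ref = importlib.resources.files("amtdr.data") / "modis_tc_coefficients.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    return TCCoefficients(
        brightness=tuple(raw["brightness"]),
        greenness=tuple(raw["greenness"]),
        wetness=tuple(raw["wetness"]),
        band_order=tuple(raw["band_order"]),
        version=str(raw.get("version", "unknown")),
    )


def compute_ndvi(red: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """(NIR - red)/(NIR + red); NaN where the denominator is zero."""
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = (nir - red) / denom
    return np.where(denom != 0, ndvi, np.nan)


def compute_nirv(red: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """NIRv = NDVI x NIR reflectance."""
    return compute_ndvi(red, nir) * np.asarray(nir, dtype=float)


def compute_tasseled_cap(
    reflectance: np.ndarray,
    coefficients: TCCoefficients | None = None,
    band_axis: int = -1,
) -> np.ndarray:
    """Raw tasseled-cap components (B, G, W) of 7-band reflectance.

    ``reflectance`` may be a single 7-vector or any array with a 7-long
    band axis.  NaN in any band propagates to all three components of
    that sample.  Returns an array with the band axis replaced by a
    3-long component axis (B, G, W).
    """
    if coefficients is None:
        coefficients = load_tc_coefficients()
    refl = np.asarray(reflectance, dtype=float)
    refl = np.moveaxis(refl, band_axis, -1)
    if refl.shape[-1] != 7:
        raise ValueError("expected 7 bands on the band axis")
    tc = refl @ coefficients.matrix.T
    bad = np.any(np.isnan(refl), axis=-1)
    if np.any(bad):
        tc = np.where(bad[..., None], np.nan, tc)
    return np.moveaxis(tc, -1, band_axis)


@dataclass(frozen=True)
class StandardizationStats:
    """Mean/SD of raw B, G, W over a vegetation reference set.

    SDs use the n-1 (sample) denominator.  ``provenance`` records how the
    reference set was chosen so a persisted file is self-describing.
    """

    mean: tuple  # (B_mu, G_mu, W_mu)
    sd: tuple  # (B_sigma, G_sigma, W_sigma)
    n_reference: int
    provenance: str = ""

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "StandardizationStats":
        raw = json.loads(Path(path).read_text())
        return cls(
            mean=tuple(raw["mean"]),
            sd=tuple(raw["sd"]),
            n_reference=int(raw["n_reference"]),
            provenance=raw.get("provenance", ""),
        )


def fit_standardization(
    tc_values: np.ndarray, provenance: str = ""
) -> StandardizationStats:
    """Fit per-component mean and sample SD over a reference set.

    ``tc_values`` has shape ``(n_samples, 3)`` in (B, G, W) order; NaN
    rows are dropped.  A zero-variance component raises, naming the
    component.
    """
    tc = np.asarray(tc_values, dtype=float)
    if tc.ndim != 2 or tc.shape[1] != 3:
        raise ValueError("tc_values must have shape (n_samples, 3)")
    tc = tc[np.all(np.isfinite(tc), axis=1)]
    if tc.shape[0] < 2:
        raise ValueError("reference set needs at least 2 valid samples")
    mean = tc.mean(axis=0)
    sd = tc.std(axis=0, ddof=1)
    for name, s in zip(_COMPONENTS, sd):
        if s == 0:
            raise ValueError(f"zero variance in reference {name}; cannot standardize")
    return StandardizationStats(
        mean=tuple(float(x) for x in mean),
        sd=tuple(float(x) for x in sd),
        n_reference=int(tc.shape[0]),
        provenance=provenance,
    )


def standardize_tc(
    tc: np.ndarray, stats: StandardizationStats, component_axis: int = -1
) -> np.ndarray:
    """z-score raw (B, G, W) with fitted reference stats."""
    arr = np.asarray(tc, dtype=float)
    arr = np.moveaxis(arr, component_axis, -1)
    if arr.shape[-1] != 3:
        raise ValueError("expected 3 components on the component axis")
    out = (arr - np.asarray(stats.mean)) / np.asarray(stats.sd)
    return np.moveaxis(out, -1, component_axis)


def compute_di(
    tc: np.ndarray,
    stats: StandardizationStats | None = None,
    component_axis: int = -1,
    standardized: bool = False,
) -> np.ndarray:
    """DI = B_r - (G_r + W_r).

    Pass raw components plus ``stats``, or already-standardized
    components with ``standardized=True``.
    """
    if standardized:
        z = np.moveaxis(np.asarray(tc, dtype=float), component_axis, -1)
        if z.shape[-1] != 3:
            raise ValueError("expected 3 components on the component axis")
    else:
        if stats is None:
            raise ValueError("standardization stats are required for raw components")
        z = np.moveaxis(standardize_tc(tc, stats, component_axis), component_axis, -1)
    return z[..., 0] - (z[..., 1] + z[..., 2])


def _season_slice(doy: np.ndarray) -> np.ndarray:
    lo, hi = GROWING_SEASON
    return (doy >= lo) & (doy <= hi)


def compute_ga(nirv_daily: np.ndarray, doy: np.ndarray | None = None) -> float:
    """Greening abundance of one pixel-year.

    ``nirv_daily`` is the daily NIRv profile; ``doy`` the matching
    day-of-year vector (defaults to 1..365, in which case the 365-day
    profile is windowed to May-September internally).  GA is the mean of
    the profile over the inclusive span between the dates of the window
    minimum and maximum (either order; ties broken by the earliest
    date).  Returns NaN when the window holds no valid value.
    """
    v = np.asarray(nirv_daily, dtype=float)
    if v.ndim != 1:
        raise ValueError("nirv_daily must be 1-D (one pixel-year)")
    if doy is None:
        doy = np.arange(1, v.size + 1)
    doy = np.asarray(doy)
    window = _season_slice(doy)
    v = v[window]
    if v.size == 0 or not np.any(np.isfinite(v)):
        return float("nan")
    finite = np.isfinite(v)
    idx = np.flatnonzero(finite)
    i_min = idx[np.nanargmin(v[idx])]
    i_max = idx[np.nanargmax(v[idx])]
    a, b = sorted((i_min, i_max))
    return float(np.nanmean(v[a : b + 1]))


def ga_for_grid(nirv_daily: np.ndarray, doy: np.ndarray | None = None) -> np.ndarray:
    """Vectorised GA over a ``(n_days, rows, cols)`` daily NIRv cube."""
    v = np.asarray(nirv_daily, dtype=float)
    if v.ndim != 3:
        raise ValueError("expected (n_days, rows, cols)")
    if doy is None:
        doy = np.arange(1, v.shape[0] + 1)
    window = _season_slice(np.asarray(doy))
    w = v[window]  # (n_win, rows, cols)
    n_win = w.shape[0]
    flat = w.reshape(n_win, -1)
    out = np.full(flat.shape[1], np.nan)
    any_valid = np.any(np.isfinite(flat), axis=0)
    cols = np.flatnonzero(any_valid)
    if cols.size:
        sub = flat[:, cols]
        i_min = np.nanargmin(sub, axis=0)
        i_max = np.nanargmax(sub, axis=0)
        lo = np.minimum(i_min, i_max)
        hi = np.maximum(i_min, i_max)
        # inclusive span mean via cumulative sums of values and counts
        filled = np.nan_to_num(sub, nan=0.0)
        counts = np.isfinite(sub).astype(np.int64)
        csum = np.vstack([np.zeros(sub.shape[1]), np.cumsum(filled, axis=0)])
        ccnt = np.vstack([np.zeros(sub.shape[1], dtype=np.int64), np.cumsum(counts, axis=0)])
        j = np.arange(sub.shape[1])
        tot = csum[hi + 1, j] - csum[lo, j]
        cnt = ccnt[hi + 1, j] - ccnt[lo, j]
        out[cols] = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    return out.reshape(v.shape[1:])


def features_for_year(
    daily_bands: np.ndarray,
    stats: StandardizationStats,
    coefficients: TCCoefficients | None = None,
    doy: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Per-pixel feature grids for one year of daily reflectance.

    ``daily_bands`` has shape ``(n_days, 7, rows, cols)``.  Returns a
    dict of ``(rows, cols)`` grids: the 15 classifier features
    (:data:`FEATURE_NAMES`), ``ga``, ``di`` (growing-season mean of the
    daily DI — the annual DI), and ``valid`` (True where every feature
    is finite).
    """
    if coefficients is None:
        coefficients = load_tc_coefficients()
    v = np.asarray(daily_bands, dtype=float)
    if v.ndim != 4 or v.shape[1] != 7:
        raise ValueError("expected (n_days, 7, rows, cols)")
    n_days = v.shape[0]
    if doy is None:
        doy = np.arange(1, n_days + 1)
    window = _season_slice(np.asarray(doy))

    nirv = compute_nirv(v[:, 0], v[:, 1])  # (days, rows, cols)
    tc = compute_tasseled_cap(v, coefficients, band_axis=1)  # (days, 3, rows, cols)
    di_daily = compute_di(tc, stats, component_axis=1)

    season = {
        "nirv": nirv[window],
        "di": di_daily[window],
        "tc1": tc[:, 0][window],
        "tc2": tc[:, 1][window],
        "tc3": tc[:, 2][window],
    }
    out: dict[str, np.ndarray] = {}
    with np.errstate(all="ignore"):
        for var, cube in season.items():
            out[f"{var}_max"] = np.nanmax(cube, axis=0)
            out[f"{var}_min"] = np.nanmin(cube, axis=0)
            out[f"{var}_mean"] = np.nanmean(cube, axis=0)
    out["ga"] = ga_for_grid(nirv, doy)
    out["di"] = out["di_mean"]
    out["valid"] = np.all(
        [np.isfinite(out[name]) for name in FEATURE_NAMES + ["ga"]], axis=0
    )
    return out


def feature_table(
    per_year: dict[int, dict[str, np.ndarray]],
) -> pd.DataFrame:
    """Stack per-year feature grids into a long (pixel, year) table."""
    frames = []
    for year, grids in sorted(per_year.items()):
        rows, cols = grids["ga"].shape
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        rec = {
            "pixel_id": (rr * cols + cc).ravel(),
            "row": rr.ravel(),
            "col": cc.ravel(),
            "year": year,
        }
        for name in FEATURE_NAMES:
            rec[name] = grids[name].ravel()
        rec["ga"] = grids["ga"].ravel()
        rec["di"] = grids["di"].ravel()
        rec["valid"] = grids["valid"].ravel()
        frames.append(pd.DataFrame(rec))
    return pd.concat(frames, ignore_index=True)
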