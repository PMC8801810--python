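"""Per-pixel interannual trend estimation and significance testing.

Disturbance-change analysis rests on two non-parametric statistics applied
to short annual series (typically 17 values, one per year) of the
disturbance index (DI) and greening abundance (GA):

* the Theil–Sen slope — the median of all pairwise slopes
  ``(y_j - y_i) / (t_j - t_i)``, a robust estimate of the trend magnitude
  in variable units per year;
* the Mann–Kendall test — a rank-based test for monotonic trend with
  statistic ``S``, tie-corrected variance, continuity-corrected normal
  deviate ``Z`` and a two-sided p-value.

Both are implemented vectorised over pixels so that whole rasters of
annual series are processed in one call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

__all__ = [
    "TrendResult",
    "sen_slope",
    "mann_kendall",
    "trend_analysis",
    "MIN_SERIES_LENGTH",
    "DEFAULT_ALPHA",
]

#: Minimum number of valid annual values required for the Mann–Kendall test.
MIN_SERIES_LENGTH = 4

#: Conventional two-sided significance level; overridable in every API.
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class TrendResult:
    """Trend summary for one annual series.

    ``sen_slope`` is in variable units per year.  ``mk_s`` is the integer
    Mann–Kendall statistic, ``mk_z`` its continuity-corrected normal
    deviate, ``p_value`` the two-sided p.  ``direction`` is "+", "-" or
    "0" from the Sen slope sign (falling back to the sign of S when the
    slope is exactly zero).  ``valid`` is False when the series was too
    short, in which case all statistics are NaN.
    """

    sen_slope: float
    mk_s: float
    mk_z: float
    p_value: float
    significant: bool
    direction: str
    n: int
    alpha: float = DEFAULT_ALPHA
    valid: bool = True

    @classmethod
    def invalid(cls, n: int = 0, alpha: float = DEFAULT_ALPHA) -> "TrendResult":
        return cls(np.nan, np.nan, np.nan, np.nan, False, "0", n, alpha, False)


def _as_2d(values: np.ndarray) -> tuple[np.ndarray, bool]:
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        return values[None, :], True
    if values.ndim == 2:
        return values, False
    raise ValueError("values must be 1-D (one series) or 2-D (series, years)")


def sen_slope(values: np.ndarray, years: np.ndarray | None = None) -> np.ndarray | float:
    """Theil–Sen slope: median of all pairwise slopes over valid pairs.

    ``values`` may be one series (1-D) or a stack of series (2-D,
    ``(n_series, n_years)``).  NaN entries are treated as missing; a
    series with fewer than two valid points yields NaN.
    """
    v, squeeze = _as_2d(values)
    n = v.shape[1]
    t = np.arange(n, dtype=float) if years is None else np.asarray(years, dtype=float)
    if t.shape != (n,):
        raise ValueError("years must match the series length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("years must be strictly increasing")

    iu, ju = np.triu_indices(n, k=1)
    dt = t[ju] - t[iu]
    pair_slopes = (v[:, ju] - v[:, iu]) / dt  # NaN where either point missing
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> NaN
        slopes = np.nanmedian(pair_slopes, axis=1)
    n_valid = np.sum(np.isfinite(v), axis=1)
    slopes = np.where(n_valid >= 2, slopes, np.nan)
    return float(slopes[0]) if squeeze else slopes


def _mk_core(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (S, Var(S)) per series for a 2-D stack with NaN missing values."""
    n_series, n = v.shape
    iu, ju = np.triu_indices(n, k=1)
    diff = v[:, ju] - v[:, iu]
    with np.errstate(invalid="ignore"):
        s = np.nansum(np.sign(diff), axis=1)

    m = np.sum(np.isfinite(v), axis=1).astype(float)
    var = m * (m - 1) * (2 * m + 5) / 18.0

    # tie correction: subtract t(t-1)(2t+5)/18 per tied group
    for k in range(n_series):
        row = v[k][np.isfinite(v[k])]
        if row.size < 2:
            continue
        _, counts = np.unique(row, return_counts=True)
        ties = counts[counts > 1]
        if ties.size:
            var[k] -= np.sum(ties * (ties - 1) * (2 * ties + 5)) / 18.0
    return s, var


def mann_kendall(
    values: np.ndarray,
    years: np.ndarray | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> TrendResult | dict[str, np.ndarray]:
    """Mann–Kendall trend test with tie-corrected variance and continuity
    correction.

    For a single 1-D series returns a :class:`TrendResult`; for a 2-D
    stack returns a dict of arrays with keys ``sen_slope``, ``s``, ``z``,
    ``p``, ``significant``, ``n_valid``, ``valid``.

    The normal deviate uses the standard continuity correction:
    ``Z = (S - 1)/sqrt(Var)`` if ``S > 0``, ``(S + 1)/sqrt(Var)`` if
    ``S < 0`` and 0 otherwise; p is two-sided.  Series with fewer than
    :data:`MIN_SERIES_LENGTH` valid values are flagged invalid (NaN
    statistics) rather than tested.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    v, squeeze = _as_2d(values)
    n = v.shape[1]
    if years is not None:
        years = np.asarray(years, dtype=float)
        if years.shape != (n,):
            raise ValueError("years must match the series length")
        if np.any(np.diff(years) <= 0):
            raise ValueError("years must be strictly increasing")

    s, var = _mk_core(v)
    n_valid = np.sum(np.isfinite(v), axis=1)
    ok = n_valid >= MIN_SERIES_LENGTH

    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(s > 0, (s - 1), np.where(s < 0, (s + 1), 0.0)) / np.sqrt(var)
    z = np.where(var > 0, z, 0.0)
    p = 2.0 * _stats.norm.sf(np.abs(z))
    slope = sen_slope(v, years)
    slope = np.atleast_1d(slope)

    s_f = np.where(ok, s.astype(float), np.nan)
    z_f = np.where(ok, z, np.nan)
    p_f = np.where(ok, p, np.nan)
    sig = ok & (p < alpha)

    if squeeze:
        if not ok[0]:
            return TrendResult.invalid(int(n_valid[0]), alpha)
        sl = float(slope[0])
        if sl > 0:
            direction = "+"
        elif sl < 0:
            direction = "-"
        else:
            direction = "+" if s_f[0] > 0 else ("-" if s_f[0] < 0 else "0")
        return TrendResult(
            sen_slope=sl,
            mk_s=float(s_f[0]),
            mk_z=float(z_f[0]),
            p_value=float(p_f[0]),
            significant=bool(sig[0]),
            direction=direction,
            n=int(n_valid[0]),
            alpha=alpha,
        )
    return {
        "sen_slope": np.where(ok, slope, np.nan),
        "s": s_f,
        "z": z_f,
        "p": p_f,
        "significant": sig,
        "n_valid": n_valid,
        "valid": ok,
    }


def trend_analysis(
    annual: np.ndarray,
    years: np.ndarray | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, np.ndarray]:
    """Trend statistics for a raster of annual series.

    ``annual`` has shape ``(n_years, rows, cols)`` (NaN = missing).
    Returns per-pixel arrays (``rows, cols``) for slope, S, Z, p and the
    significance mask.
    """
    annual = np.asarray(annual, dtype=float)
    if annual.ndim != 3:
        raise ValueError("annual must have shape (n_years, rows, cols)")
    n_years, rows, cols = annual.shape
    flat = annual.reshape(n_years, -1).T  # (pixels, years)
    res = mann_kendall(flat, years, alpha)
    out = {}
    for key in ("sen_slope", "s", "z", "p"):
        out[key] = res[key].reshape(rows, cols)
    out["significant"] = res["significant"].reshape(rows, cols)
    out["valid"] = res["valid"].reshape(rows, cols)
    return out
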