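"""Quality masking and temporal densification of reflectance stacks.

Two steps precede all index computation:

1. QA masking — any 8-day composite flagged as cloud-contaminated is
   set to nodata (NaN), leaving clean values untouched.
2. Daily interpolation — each pixel-year's surviving composites are
   linearly interpolated to a 365-day series.  Interpolation is exact
   at the retained composite dates; days before the first (after the
   last) valid composite of the year take the nearest valid value, so
   no extrapolated reflectance can leave [0, 1].

A pixel-year with fewer than two valid composites is flagged invalid
and left NaN rather than fabricated.

QA dialects: synthetic stacks carry a single boolean "contaminated"
bit.  ``QA_DECODERS`` is the hook for real-sensor state-flag decoders;
only the boolean decoder is implemented.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import DAYS_PER_YEAR, DailySeries, ReflectanceStack

__all__ = ["apply_qa_mask", "interpolate_daily", "interpolate_year", "QA_DECODERS"]

log = logging.getLogger(__name__)


def _boolean_decoder(qa: np.ndarray) -> np.ndarray:
    return np.asarray(qa, dtype=bool)


#: name -> callable(qa_array) -> boolean "contaminated" mask
QA_DECODERS = {"boolean": _boolean_decoder}


def apply_qa_mask(stack: ReflectanceStack, decoder: str = "boolean") -> ReflectanceStack:
    """Set QA-flagged pixel-epochs to nodata; leave the rest unchanged.

    Pixels whose every epoch is flagged are logged as wholly invalid
    (they fall out downstream via the <2-valid-composites rule).
    """
    try:
        contaminated = QA_DECODERS[decoder](stack.qa)
    except KeyError:
        raise ValueError(f"unknown QA decoder {decoder!r}") from None
    refl = np.array(stack.reflectance, dtype=float, copy=True)
    refl[contaminated[:, None, :, :] & np.ones((1, stack.n_bands, 1, 1), dtype=bool)] = np.nan
    dead = np.all(contaminated, axis=0)
    if np.any(dead):
        log.warning("%d pixel(s) have every epoch QA-flagged; excluded downstream", int(dead.sum()))
    return ReflectanceStack(
        reflectance=refl,
        qa=stack.qa.copy(),
        years=stack.years.copy(),
        doy=stack.doy.copy(),
        transform=stack.transform,
        crs=stack.crs,
    )


def _interp_to_daily(values: np.ndarray, knot_doy: np.ndarray) -> np.ndarray:
    """Linear interpolation of knot values to days 1..365, vectorised
    over trailing sample axes.

    ``values``: ``(n_knots, n_samples)`` with NaN = missing knots.
    Missing leading/trailing spans take the nearest valid value.
    Samples with no valid knot stay NaN.
    """
    n_knots, n_samples = values.shape
    full = np.full((DAYS_PER_YEAR, n_samples), np.nan)
    full[knot_doy - 1, :] = values
    valid = np.isfinite(full)
    day_idx = np.arange(DAYS_PER_YEAR)[:, None]

    prev = np.where(valid, day_idx, -1)
    prev = np.maximum.accumulate(prev, axis=0)
    nxt = np.where(valid, day_idx, DAYS_PER_YEAR)
    nxt = np.minimum.accumulate(nxt[::-1], axis=0)[::-1]

    has_prev = prev >= 0
    has_next = nxt < DAYS_PER_YEAR
    prev_c = np.where(has_prev, prev, 0)
    nxt_c = np.where(has_next, nxt, DAYS_PER_YEAR - 1)
    cols = np.arange(n_samples)[None, :]
    v_prev = full[prev_c, cols]
    v_next = full[nxt_c, cols]

    span = nxt_c - prev_c
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(span > 0, (day_idx - prev_c) / np.maximum(span, 1), 0.0)
    both = has_prev & has_next
    out = np.where(both, v_prev + frac * (v_next - v_prev), np.nan)
    out = np.where(has_prev & ~has_next, v_prev, out)
    out = np.where(~has_prev & has_next, v_next, out)
    return out


def interpolate_year(stack: ReflectanceStack, year: int) -> tuple[np.ndarray, np.ndarray]:
    """Daily (365, n_bands, rows, cols) series for one year.

    Returns ``(daily, valid)`` where ``valid`` is the (rows, cols) mask
    of pixel-years with at least two valid composites.  QA-flagged
    epochs are excluded even if :func:`apply_qa_mask` was not called.
    """
    idx = stack.epochs_of_year(year)
    if idx.size == 0:
        raise ValueError(f"stack has no epochs in year {year}")
    rows, cols = stack.grid_shape
    n_bands = stack.n_bands
    refl = np.asarray(stack.reflectance[idx], dtype=float)  # (E, B, r, c)
    contaminated = stack.qa[idx]  # (E, r, c)
    refl = np.where(contaminated[:, None, :, :], np.nan, refl)
    knot_doy = stack.doy[idx]

    n_valid = np.sum(np.all(np.isfinite(refl), axis=1), axis=0)  # (r, c)
    valid = n_valid >= 2

    daily = np.empty((DAYS_PER_YEAR, n_bands, rows, cols), dtype=float)
    for b in range(n_bands):
        flat = refl[:, b].reshape(idx.size, -1)
        daily[:, b] = _interp_to_daily(flat, knot_doy).reshape(DAYS_PER_YEAR, rows, cols)
    daily[:, :, ~valid] = np.nan
    return daily, valid


def interpolate_daily(stack: ReflectanceStack, years=None) -> DailySeries:
    """Daily series for all (or selected) years of a stack.

    Memory scales as ``n_years x 365 x n_bands x rows x cols``; for
    large grids prefer :func:`interpolate_year` inside a loop.
    """
    years = stack.year_list if years is None else list(years)
    rows, cols = stack.grid_shape
    values = np.empty((len(years), DAYS_PER_YEAR, stack.n_bands, rows, cols), dtype=float)
    valid = np.empty((len(years), rows, cols), dtype=bool)
    for i, year in enumerate(years):
        values[i], valid[i] = interpolate_year(stack, year)
    return DailySeries(values=values, valid=valid, years=years)
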