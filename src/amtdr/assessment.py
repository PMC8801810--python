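"""Accuracy assessment and driver analyses.

Covers the map-validation side of the workflow (confusion matrix,
overall accuracy, Cohen's kappa, producer's and user's accuracy) and
the influence-factor analyses: correlation of annual DI with climate or
livestock series, and binning of annual grassland DI by elevation.

All percentage statistics are computed with exact rational arithmetic
on the integer counts (via :class:`fractions.Fraction`) before any
rounding, so printed two-decimal values are reproducible exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "ConfusionMatrix",
    "confusion_and_kappa",
    "correlate_trends",
    "elevation_profile",
]


@dataclass
class ConfusionMatrix:
    """Reference-vs-predicted counts with derived accuracy statistics.

    Rows are reference classes, columns predicted classes.  Accuracies
    are percentages in [0, 100]; kappa is dimensionless in [-1, 1].
    """

    labels: list
    counts: np.ndarray  # (n_classes, n_classes) int, reference rows
    overall_accuracy: float = field(init=False)
    kappa: float = field(init=False)
    producers_accuracy: np.ndarray = field(init=False)
    users_accuracy: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if c.shape[0] != len(self.labels):
            raise ValueError("labels must match matrix size")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        n = int(c.sum())
        if n == 0:
            raise ValueError("empty confusion matrix")
        self.counts = c
        self.n = n

        trace = int(np.trace(c))
        row = c.sum(axis=1)
        col = c.sum(axis=0)

        oa = Fraction(trace, n)
        pe = sum(Fraction(int(r) * int(k), n * n) for r, k in zip(row, col))
        self.overall_accuracy = float(oa * 100)
        if pe == 1:
            self.kappa = float("nan")  # degenerate marginals: kappa undefined
        else:
            self.kappa = float((oa - pe) / (1 - pe))
        with np.errstate(invalid="ignore", divide="ignore"):
            self.producers_accuracy = np.where(row > 0, np.diag(c) / row, np.nan) * 100
            self.users_accuracy = np.where(col > 0, np.diag(c) / col, np.nan) * 100

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.labels, columns=self.labels)
        df.index.name = "reference"
        df.columns.name = "predicted"
        return df

    def report(self, decimals: int = 2) -> str:
        lines = [self.to_frame().to_string(), ""]
        for lab, pa, ua in zip(self.labels, self.producers_accuracy, self.users_accuracy):
            lines.append(
                f"{lab}: producer's accuracy {pa:.{decimals}f}%  "
                f"user's accuracy {ua:.{decimals}f}%"
            )
        lines.append(f"overall accuracy {self.overall_accuracy:.{decimals}f}%")
        lines.append(f"kappa {self.kappa:.3f}")
        return "\n".join(lines)


def confusion_and_kappa(reference, predicted, labels=None) -> ConfusionMatrix:
    """Build a :class:`ConfusionMatrix` from paired label sequences.

    ``labels`` fixes the class order; by default the sorted union of the
    observed labels is used.
    """
    reference = np.asarray(reference).ravel()
    predicted = np.asarray(predicted).ravel()
    if reference.size == 0:
        raise ValueError("empty label lists")
    if reference.shape != predicted.shape:
        raise ValueError("reference and predicted must have equal length")
    if labels is None:
        labels = sorted(set(reference.tolist()) | set(predicted.tolist()))
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for r, p in zip(reference, predicted):
        counts[index[r], index[p]] += 1
    return ConfusionMatrix(labels, counts)


def correlate_trends(
    di_series,
    driver_series,
    use_differences: bool = False,
) -> tuple[float, float]:
    """Pearson correlation between an annual DI series and a driver series.

    With ``use_differences=True`` the correlation is computed on per-year
    first differences instead of the value series.  Returns ``(r, p)``;
    a zero-variance input yields ``(nan, nan)``.
    """
    x = np.asarray(di_series, dtype=float)
    y = np.asarray(driver_series, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if use_differences:
        x, y = np.diff(x), np.diff(y)
    if x.size < 3:
        raise ValueError("need at least 3 paired years")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = _stats.pearsonr(x, y)
    return float(r), float(p)


def elevation_profile(
    di_annual: np.ndarray,
    dem: np.ndarray,
    grassland_mask: np.ndarray,
    bin_edges=None,
    years=None,
) -> pd.DataFrame:
    """Mean and SD of annual grassland DI per elevation bin.

    ``di_annual`` has shape ``(n_years, rows, cols)``; ``dem`` is metres
    above sea level on the same grid.  Default bins run in 500-m steps
    from below 1,000 m to above 6,000 m (open-ended end bins).  Bins form
    a partition of the valid grassland pixels; empty bins are kept in the
    table with ``count`` 0 and NaN statistics, flagged by ``empty``.
    """
    di_annual = np.asarray(di_annual, dtype=float)
    dem = np.asarray(dem, dtype=float)
    grassland_mask = np.asarray(grassland_mask, dtype=bool)
    if di_annual.ndim != 3:
        raise ValueError("di_annual must have shape (n_years, rows, cols)")
    if dem.shape != di_annual.shape[1:] or grassland_mask.shape != dem.shape:
        raise ValueError("dem/mask must match the DI grid")
    if bin_edges is None:
        bin_edges = [-np.inf, *range(1000, 6001, 500), np.inf]
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if bin_edges[0] > np.nanmin(dem[grassland_mask]) or bin_edges[-1] < np.nanmax(
        dem[grassland_mask]
    ):
        raise ValueError("bin edges must cover the DEM range over the mask")
    n_years = di_annual.shape[0]
    if years is None:
        years = np.arange(n_years)

    # right-open bins [e_k, e_{k+1}); final bin closed on the right
    bin_index = np.digitize(dem, bin_edges[1:-1], right=False)
    rows = []
    for k in range(len(bin_edges) - 1):
        in_bin = grassland_mask & (bin_index == k)
        lo, hi = bin_edges[k], bin_edges[k + 1]
        label = (
            f"<{hi:.0f}" if np.isneginf(lo) else (f">={lo:.0f}" if np.isposinf(hi) else f"{lo:.0f}-{hi:.0f}")
        )
        for yi in range(n_years):
            vals = di_annual[yi][in_bin]
            vals = vals[np.isfinite(vals)]
            rows.append(
                {
                    "bin": label,
                    "bin_low": lo,
                    "bin_high": hi,
                    "year": years[yi],
                    "count": int(vals.size),
                    "di_mean": float(np.mean(vals)) if vals.size else np.nan,
                    "di_sd": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
                    "empty": vals.size == 0,
                }
            )
    return pd.DataFrame(rows)
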