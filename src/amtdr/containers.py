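"""Core gridded containers shared across the pipeline.

A :class:`ReflectanceStack` holds an 8-day composite multiband
reflectance time series (MODIS MOD09A1-like: 7 bands, 46 epochs per
year) with a per-pixel-epoch QA flag; a :class:`DailySeries` holds the
365-day densified series for one or more years.  Missing data are NaN
throughout; integer class rasters use the code table below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CLASS_CODES",
    "CLASS_NAMES",
    "NODATA_CODE",
    "EPOCHS_PER_YEAR",
    "DAYS_PER_YEAR",
    "epoch_doy",
    "ReflectanceStack",
    "DailySeries",
]

#: Integer class codes used in every class-map raster.
CLASS_CODES = {"grassland": 1, "forest": 2, "bare_soil": 3, "water": 4}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}
NODATA_CODE = 0

EPOCHS_PER_YEAR = 46
#: The year is always represented as 365 days; leap-day observations are
#: merged onto day-of-year 59.
DAYS_PER_YEAR = 365


def epoch_doy(epochs_per_year: int = EPOCHS_PER_YEAR) -> np.ndarray:
    """Start day-of-year of each 8-day composite epoch (1, 9, ... 361)."""
    return 1 + 8 * np.arange(epochs_per_year)


@dataclass
class ReflectanceStack:
    """Gridded multiband reflectance time series with QA flags.

    ``reflectance`` has shape ``(n_epochs, n_bands, rows, cols)`` with
    values in [0, 1] or NaN (nodata).  ``qa`` is True where the epoch is
    cloud-contaminated.  ``years``/``doy`` give each epoch's calendar
    year and start day-of-year; epochs are strictly increasing in time.
    ``transform`` is a GDAL-style geotransform, ``crs`` a CRS identifier
    — carried through I/O, not interpreted.
    """

    reflectance: np.ndarray
    qa: np.ndarray
    years: np.ndarray
    doy: np.ndarray
    transform: tuple = (0.0, 1.0, 0.0, 0.0, 0.0, -1.0)
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance)
        self.qa = np.asarray(self.qa, dtype=bool)
        self.years = np.asarray(self.years, dtype=int)
        self.doy = np.asarray(self.doy, dtype=int)
        n_epochs = self.reflectance.shape[0]
        if self.qa.shape != (n_epochs, *self.grid_shape):
            raise ValueError("qa shape must be (n_epochs, rows, cols)")
        if self.years.shape != (n_epochs,) or self.doy.shape != (n_epochs,):
            raise ValueError("years/doy must have one entry per epoch")
        order = self.years.astype(np.int64) * 1000 + self.doy
        if np.any(np.diff(order) <= 0):
            raise ValueError("epochs must be strictly increasing in time")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.reflectance.shape[2], self.reflectance.shape[3]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    @property
    def year_list(self) -> list[int]:
        return sorted(set(self.years.tolist()))

    def epochs_of_year(self, year: int) -> np.ndarray:
        return np.flatnonzero(self.years == year)


@dataclass
class DailySeries:
    """Daily (365/year) values for one or more years.

    ``values`` has shape ``(n_years, 365, n_vars, rows, cols)``;
    ``valid`` flags pixel-years with at least two usable composites
    (others are all-NaN, never fabricated).
    """

    values: np.ndarray
    valid: np.ndarray  # (n_years, rows, cols)
    years: list = field(default_factory=list)
    doy: np.ndarray = field(default_factory=lambda: np.arange(1, DAYS_PER_YEAR + 1))

    def year_index(self, year: int) -> int:
        return self.years.index(year)
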