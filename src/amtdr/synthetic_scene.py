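"""Seeded MODIS-like scene simulator.

Generates everything the pipeline consumes, so every downstream stage
is testable without downloads:

* 8-day composite 7-band reflectance stacks (46 epochs/year, 17 years
  by default) built from per-class seasonal templates with additive
  Gaussian sensor noise and Bernoulli cloud contamination (QA-flagged,
  reflectance replaced by a bright cloud signature);
* land-cover truth maps over {grassland, forest, bare_soil, water};
* stratified training-point tables;
* auxiliary driver data: annual climate series, a DEM, per-district
  livestock counts with an exact target correlation against a DI series.

Seasonal templates are double-logistic curves: reflectance(band, day) =
base + amplitude x phenology(day), one May-September growing season.
Vegetation classes green up (red falls, NIR rises, wetness rises); bare
soil is bright and aseasonal; water keeps NIR below red year-round.

Trend injection
---------------
The two injected signals are exactly orthogonal by construction, so
each dial moves only the index it is meant to move:

* Disturbance drift acts in tasseled-cap space — a per-year drift
  ``delta`` moves (B, G, W) by ``delta x (+1, -1/2, -1/2)`` (brightness
  up, greenness and wetness down) — and is back-projected to the five
  non-red/NIR bands via the pseudo-inverse of the corresponding
  coefficient sub-matrix.  Red and NIR are untouched, so NIRv and GA
  are exactly unchanged while DI moves by a closed-form amount.
* Greening trends scale the seasonal amplitude of the template (raising
  or lowering peak NIRv, hence GA), and the tasseled-cap effect of that
  scaling is cancelled by a compensating adjustment of the non-red/NIR
  bands, so B, G, W — and therefore DI — are exactly unchanged.

Both dials accept a linear per-year slope or an explicit per-year
anomaly sequence.  The anomaly form exists because a "potential" change
(trend present but Mann-Kendall non-significant) cannot be made a
robust per-pixel truth with a linear drift in i.i.d. noise: no
drift/noise ratio pins both the Sen-slope sign and non-significance at
the 95% level for 17-point series.  A designed anomaly whose
deterministic Kendall S sits well inside the acceptance band is the
faithful way to simulate a genuinely "potential" signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .containers import (
    CLASS_CODES,
    CLASS_NAMES,
    EPOCHS_PER_YEAR,
    ReflectanceStack,
    epoch_doy,
)
from .indices import load_tc_coefficients

__all__ = [
    "ClassProfile",
    "TrendPatch",
    "ScenarioConfig",
    "DEFAULT_PROFILES",
    "default_class_map",
    "generate_stack",
    "truth_class_map",
    "generate_training_points",
    "generate_climate",
    "generate_dem",
    "generate_livestock",
    "generate_drivers",
    "potential_anomaly_pattern",
    "demo_disturbance_scene",
    "null_scene",
]


# --------------------------------------------------------------------------
# class profiles


@dataclass(frozen=True)
class ClassProfile:
    """Seasonal reflectance template for one land-cover class.

    ``base`` is the off-season reflectance per band, ``amplitude`` the
    peak-season additive change per band; the double-logistic phenology
    curve (start/end of season ``sos``/``eos`` in day-of-year, logistic
    rates in days) modulates the amplitude between 0 and ~1.
    """

    name: str
    base: tuple
    amplitude: tuple
    sos: float = 140.0
    eos: float = 260.0
    rate_sos: float = 10.0
    rate_eos: float = 10.0

    def phenology(self, doy: np.ndarray) -> np.ndarray:
        d = np.asarray(doy, dtype=float)
        return 1.0 / (1.0 + np.exp(-(d - self.sos) / self.rate_sos)) - 1.0 / (
            1.0 + np.exp(-(d - self.eos) / self.rate_eos)
        )

    def reflectance(self, doy: np.ndarray, amplitude_scale: float = 1.0) -> np.ndarray:
        """Template reflectance, shape ``(n_days, 7)``, clipped to [0, 1]."""
        curve = self.phenology(doy)[:, None]
        refl = np.asarray(self.base) + amplitude_scale * curve * np.asarray(self.amplitude)
        return np.clip(refl, 0.0, 1.0)


# Band order: red, nir, blue, green, nir2, swir1, swir2.
DEFAULT_PROFILES: dict[str, ClassProfile] = {
    "grassland": ClassProfile(
        name="grassland",
        base=(0.10, 0.20, 0.06, 0.09, 0.22, 0.24, 0.16),
        amplitude=(-0.05, 0.17, -0.01, 0.02, 0.06, -0.06, -0.06),
        sos=140.0,
        eos=260.0,
    ),
    "forest": ClassProfile(
        name="forest",
        base=(0.07, 0.24, 0.05, 0.07, 0.24, 0.20, 0.12),
        amplitude=(-0.03, 0.22, -0.01, 0.02, 0.08, -0.05, -0.04),
        sos=130.0,
        eos=270.0,
        rate_sos=8.0,
        rate_eos=8.0,
    ),
    "bare_soil": ClassProfile(
        name="bare_soil",
        base=(0.22, 0.27, 0.12, 0.18, 0.30, 0.34, 0.30),
        amplitude=(0.0, 0.012, 0.0, 0.004, 0.0, 0.0, 0.0),
    ),
    "water": ClassProfile(
        name="water",
        base=(0.05, 0.02, 0.08, 0.06, 0.015, 0.010, 0.008),
        amplitude=(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    ),
}


# --------------------------------------------------------------------------
# scenario configuration


@dataclass(frozen=True)
class TrendPatch:
    """Rectangular region with injected interannual change.

    ``di_slope`` is the per-year tasseled-cap drift (brightness units per
    year; greenness and wetness each move by minus half of it).
    ``ga_slope`` is the per-year fractional change of the seasonal
    amplitude.  ``di_anomaly``/``ga_anomaly`` (length n_years) override
    the linear forms with explicit per-year values.  ``to_class`` with
    ``transition_year`` switches the patch's land cover from that year
    onward (e.g. grassland turning to water).  ``label`` carries the
    designer's intended disturbance class for truth bookkeeping.
    """

    row0: int
    row1: int
    col0: int
    col1: int
    di_slope: float = 0.0
    ga_slope: float = 0.0
    di_anomaly: tuple | None = None
    ga_anomaly: tuple | None = None
    to_class: str | None = None
    transition_year: int | None = None
    label: str | None = None

    def mask(self, rows: int, cols: int) -> np.ndarray:
        m = np.zeros((rows, cols), dtype=bool)
        m[self.row0 : self.row1, self.col0 : self.col1] = True
        return m

    def di_drift(self, year_index: int) -> float:
        if self.di_anomaly is not None:
            return float(self.di_anomaly[year_index])
        return self.di_slope * year_index

    def ga_scale(self, year_index: int) -> float:
        if self.ga_anomaly is not None:
            return 1.0 + float(self.ga_anomaly[year_index])
        return 1.0 + self.ga_slope * year_index


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one synthetic scene.

    Identical (config, seed) pairs produce bit-identical output; all
    randomness flows from ``rng_seed`` through deterministically spawned
    per-component child streams.
    """

    grid_rows: int
    grid_cols: int
    years: tuple = tuple(range(2001, 2018))
    epochs_per_year: int = EPOCHS_PER_YEAR
    class_map: np.ndarray | None = None
    cloud_fraction: float = 0.05
    noise_sd: float = 0.02
    trend_patches: tuple = ()
    rng_seed: int = 0
    profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if not 0.0 <= self.cloud_fraction <= 1.0:
            raise ValueError("cloud_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.years) < 1:
            raise ValueError("need at least one year")
        covered = np.zeros((self.grid_rows, self.grid_cols), dtype=bool)
        for p in self.trend_patches:
            if not (0 <= p.row0 < p.row1 <= self.grid_rows and 0 <= p.col0 < p.col1 <= self.grid_cols):
                raise ValueError(f"trend patch {p} lies outside the grid")
            m = p.mask(self.grid_rows, self.grid_cols)
            if np.any(covered & m):
                raise ValueError("overlapping trend patches are contradictory")
            covered |= m
            for anom in (p.di_anomaly, p.ga_anomaly):
                if anom is not None and len(anom) != len(self.years):
                    raise ValueError("anomaly sequences must have one entry per year")
            if (p.to_class is None) != (p.transition_year is None):
                raise ValueError("to_class and transition_year must be given together")
            if p.to_class is not None and p.to_class not in CLASS_CODES:
                raise ValueError(f"unknown transition class {p.to_class!r}")
        if self.class_map is not None:
            cm = np.asarray(self.class_map)
            if cm.shape != (self.grid_rows, self.grid_cols):
                raise ValueError("class_map shape must match the grid")
            if not np.all(np.isin(cm, list(CLASS_NAMES))):
                raise ValueError("class_map contains unknown class codes")

    def resolved_class_map(self) -> np.ndarray:
        if self.class_map is not None:
            return np.asarray(self.class_map, dtype=np.int16)
        return default_class_map(self.grid_rows, self.grid_cols)

    def to_yaml(self, path) -> None:
        raw = {
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "years": list(self.years),
            "epochs_per_year": self.epochs_per_year,
            "cloud_fraction": self.cloud_fraction,
            "noise_sd": self.noise_sd,
            "rng_seed": self.rng_seed,
            "trend_patches": [
                {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(p).items()}
                for p in self.trend_patches
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        raw = yaml.safe_load(open(path))
        patches = tuple(
            TrendPatch(
                **{
                    k: (tuple(v) if isinstance(v, list) else v)
                    for k, v in p.items()
                }
            )
            for p in raw.pop("trend_patches", [])
        )
        raw["years"] = tuple(raw.get("years", range(2001, 2018)))
        return cls(trend_patches=patches, **raw)


def default_class_map(rows: int, cols: int) -> np.ndarray:
    """Grassland-dominant layout: grassland everywhere except a forest
    strip (left ~15% of columns), a bare-soil strip (next ~10%) and a
    water block in the bottom-right corner (~8% of the grid)."""
    cm = np.full((rows, cols), CLASS_CODES["grassland"], dtype=np.int16)
    f = max(1, int(0.15 * cols))
    b = max(1, int(0.10 * cols))
    cm[:, :f] = CLASS_CODES["forest"]
    cm[:, f : f + b] = CLASS_CODES["bare_soil"]
    wr = max(1, int(0.28 * rows))
    wc = max(1, int(0.28 * cols))
    cm[rows - wr :, cols - wc :] = CLASS_CODES["water"]
    return cm


# --------------------------------------------------------------------------
# stack generation


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def truth_class_map(config: ScenarioConfig, year: int | None = None) -> np.ndarray:
    """Ground-truth class map, honouring patch class transitions."""
    cm = config.resolved_class_map().copy()
    if year is not None:
        for p in config.trend_patches:
            if p.to_class is not None and year >= p.transition_year:
                cm[p.mask(config.grid_rows, config.grid_cols)] = CLASS_CODES[p.to_class]
    return cm


def generate_stack(config: ScenarioConfig) -> tuple[ReflectanceStack, np.ndarray]:
    """Simulate the reflectance stack; returns ``(stack, truth map)``.

    The truth map is the baseline (first-year) class map; yearly truth
    under class transitions comes from :func:`truth_class_map`.
    """
    rows, cols = config.grid_rows, config.grid_cols
    n_years = len(config.years)
    epy = config.epochs_per_year
    doy = epoch_doy(epy)
    rng_noise, rng_cloud = _child_rngs(config.rng_seed, 2)

    tc = load_tc_coefficients()
    M = tc.matrix  # (3, 7)
    # DI drift confined to the non-red/NIR bands: exact TC drift, zero
    # NIRv/GA side effect.
    pinv_rest = np.linalg.pinv(M[:, 2:])  # (5, 3)
    di_direction = np.array([1.0, -0.5, -0.5])
    band_drift_unit = np.zeros(7)
    band_drift_unit[2:] = pinv_rest @ di_direction

    base_map = config.resolved_class_map()
    code_list = sorted(CLASS_NAMES)
    templates = {
        code: config.profiles[CLASS_NAMES[code]] for code in code_list
    }

    n_epochs = n_years * epy
    refl = np.empty((n_epochs, 7, rows, cols), dtype=np.float32)
    qa = np.zeros((n_epochs, rows, cols), dtype=bool)
    years_arr = np.repeat(np.asarray(config.years, dtype=int), epy)
    doy_arr = np.tile(doy, n_years)

    for yi, year in enumerate(config.years):
        cm = truth_class_map(config, year)
        year_block = np.empty((epy, 7, rows, cols), dtype=float)
        # per-class template fill
        for code in code_list:
            sel = cm == code
            if not np.any(sel):
                continue
            t = templates[code].reflectance(doy)  # (epy, 7)
            year_block[:, :, sel] = t[:, :, None]
        # patch modifications
        for p in config.trend_patches:
            sel = p.mask(rows, cols)
            patch_cm = cm[sel]
            scale = p.ga_scale(yi)
            drift = p.di_drift(yi)
            if scale != 1.0:
                for code in np.unique(patch_cm):
                    prof = templates[int(code)]
                    t = prof.reflectance(doy, amplitude_scale=scale)
                    # cancel the tasseled-cap effect of the amplitude
                    # change on the non-red/NIR bands so DI is untouched
                    delta = t - prof.reflectance(doy)  # (epy, 7)
                    tc_effect = delta @ M.T  # (epy, 3)
                    t = t.copy()
                    t[:, 2:] -= tc_effect @ pinv_rest.T
                    sub = sel & (cm == code)
                    year_block[:, :, sub] = np.clip(t, 0.0, 1.0)[:, :, None]
            if drift != 0.0:
                year_block[:, :, sel] += (drift * band_drift_unit)[None, :, None]
        if config.noise_sd > 0:
            year_block += rng_noise.normal(0.0, config.noise_sd, size=year_block.shape)
        np.clip(year_block, 0.0, 1.0, out=year_block)
        # clouds: QA bit set, reflectance replaced by a bright signature
        if config.cloud_fraction > 0:
            cloudy = rng_cloud.random((epy, rows, cols)) < config.cloud_fraction
            if np.any(cloudy):
                bright = 0.45 + 0.1 * rng_cloud.random((epy, 7, rows, cols))
                year_block = np.where(cloudy[:, None, :, :], bright, year_block)
            qa[yi * epy : (yi + 1) * epy] = cloudy
        refl[yi * epy : (yi + 1) * epy] = year_block.astype(np.float32)

    stack = ReflectanceStack(
        reflectance=refl, qa=qa, years=years_arr, doy=doy_arr
    )
    return stack, base_map.copy()


# --------------------------------------------------------------------------
# training points


def generate_training_points(
    truth_map: np.ndarray, n_points: int, seed: int
) -> pd.DataFrame:
    """Stratified (proportional) random sample of labelled pixels.

    Sampling is without replacement; strata are the classes present in
    the truth map, with largest-remainder rounding of the proportional
    allocation.  Raises when a stratum cannot supply its allocation.
    """
    cm = np.asarray(truth_map)
    rows, cols = cm.shape
    if n_points > cm.size:
        raise ValueError("n_points exceeds the number of pixels")
    if n_points < 1:
        raise ValueError("n_points must be positive")
    rng = np.random.default_rng(seed)
    codes, counts = np.unique(cm, return_counts=True)
    keep = codes != 0
    codes, counts = codes[keep], counts[keep]
    total = counts.sum()
    exact = n_points * counts / total
    alloc = np.floor(exact).astype(int)
    remainder = exact - alloc
    for i in np.argsort(-remainder)[: n_points - alloc.sum()]:
        alloc[i] += 1
    records = []
    for code, k, avail in zip(codes, alloc, counts):
        if k > avail:
            raise ValueError(
                f"stratum {CLASS_NAMES.get(int(code), code)} has {avail} pixels, "
                f"cannot supply {k}"
            )
        flat = np.flatnonzero(cm.ravel() == code)
        chosen = rng.choice(flat, size=k, replace=False)
        records.append(
            pd.DataFrame(
                {
                    "row": chosen // cols,
                    "col": chosen % cols,
                    "class_code": int(code),
                    "class_name": CLASS_NAMES.get(int(code), str(code)),
                }
            )
        )
    df = pd.concat(records, ignore_index=True)
    df["pixel_id"] = df["row"] * cols + df["col"]
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )


# --------------------------------------------------------------------------
# drivers: climate, DEM, livestock


def generate_climate(
    years,
    base: float,
    trend: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    value_range: tuple | None = None,
) -> pd.DataFrame:
    """Annual climate series ``base + trend*(t - t0) + noise``.

    If ``value_range=(lo, hi)`` is given, the series is affinely mapped
    so its minimum and maximum equal the requested range exactly
    (emulating a region whose printed climate range is known).
    """
    years = np.asarray(list(years), dtype=int)
    rng = np.random.default_rng(seed)
    t = years - years[0]
    v = base + trend * t + rng.normal(0.0, noise_sd, size=years.size)
    if value_range is not None:
        lo, hi = value_range
        if hi <= lo:
            raise ValueError("value_range must be increasing")
        vmin, vmax = v.min(), v.max()
        if vmax == vmin:
            v = np.full_like(v, 0.5 * (lo + hi))
        else:
            v = lo + (v - vmin) * (hi - lo) / (vmax - vmin)
    return pd.DataFrame({"year": years, "value": v})


def generate_dem(
    rows: int,
    cols: int,
    seed: int = 0,
    min_elevation: float = 500.0,
    max_elevation: float = 6500.0,
    noise_sd: float = 50.0,
) -> np.ndarray:
    """Elevation raster banded along rows from low to high altitude."""
    rng = np.random.default_rng(seed)
    ramp = np.linspace(min_elevation, max_elevation, rows)[:, None]
    dem = ramp + rng.normal(0.0, noise_sd, size=(rows, cols))
    return np.clip(dem, min(0.0, min_elevation), None)


def generate_livestock(
    di_series,
    correlation: float,
    seed: int = 0,
    mean: float = 1e5,
    sd: float = 1e4,
) -> np.ndarray:
    """Annual livestock head counts with an exact sample Pearson
    correlation against the supplied DI series.

    The noise component is orthogonalised against the DI series, so the
    sample correlation equals ``correlation`` to machine precision
    (the |rho|=1 cases degenerate to an exact linear map).
    """
    if not -1.0 <= correlation <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    x = np.asarray(di_series, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("di_series must be 1-D with at least 3 years")
    if np.ptp(x) == 0:
        raise ValueError("di_series has zero variance")
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    xu = xc / np.linalg.norm(xc)
    if abs(correlation) == 1.0:
        z = np.sign(correlation) * xu
    else:
        e = rng.standard_normal(x.size)
        e -= e.mean()
        e -= (e @ xu) * xu
        e /= np.linalg.norm(e)
        z = correlation * xu + np.sqrt(1.0 - correlation**2) * e
    z = z / z.std(ddof=0) if z.std(ddof=0) > 0 else z
    return mean + sd * z


def generate_drivers(
    config: ScenarioConfig,
    seed: int,
    di_series=None,
    livestock_correlation: float = 0.8,
    regions: tuple = ("tibet", "qinghai"),
) -> dict:
    """Bundle of driver data sets aligned with a scenario.

    Returns a dict with ``climate`` (region/year/temperature/
    precipitation table), ``dem`` (raster) and, when a DI series is
    supplied, ``livestock`` (district/year/head_count table with the
    requested DI correlation)."""
    seeds = np.random.SeedSequence(seed).spawn(4)
    ranges = {
        "tibet": {"temperature": (-0.36, 1.79), "precipitation": (294.88, 494.23)},
        "qinghai": {"temperature": (-1.71, -0.47), "precipitation": (273.11, 471.60)},
    }
    temp_seeds = seeds[0].spawn(len(regions))
    prec_seeds = seeds[1].spawn(len(regions))
    frames = []
    for i, region in enumerate(regions):
        r = ranges.get(region, {"temperature": (-1.0, 1.0), "precipitation": (250.0, 500.0)})
        temp = generate_climate(
            config.years, base=0.0, trend=0.05, noise_sd=0.3,
            seed=temp_seeds[i], value_range=r["temperature"],
        )
        prec = generate_climate(
            config.years, base=0.0, trend=2.0, noise_sd=30.0,
            seed=prec_seeds[i], value_range=r["precipitation"],
        )
        frames.append(
            pd.DataFrame(
                {
                    "region": region,
                    "year": list(config.years),
                    "temperature": temp["value"].to_numpy(),
                    "precipitation": prec["value"].to_numpy(),
                }
            )
        )
    out = {
        "climate": pd.concat(frames, ignore_index=True),
        "dem": generate_dem(config.grid_rows, config.grid_cols, seed=seeds[2]),
    }
    if di_series is not None:
        counts = generate_livestock(di_series, livestock_correlation, seed=seeds[3])
        out["livestock"] = pd.DataFrame(
            {
                "district": "district_1",
                "year": list(config.years)[: len(counts)],
                "head_count": counts,
            }
        )
    return out


# --------------------------------------------------------------------------
# designed anomaly for "potential" (non-significant) trends


# Designed 17-year sequence whose deterministic Kendall S (= 20) sits
# well inside the two-sided 5% non-significance band (|S| < 50) while
# the Theil-Sen slope (0.029 per year in pattern units) is strictly
# positive, with both properties robust to additive noise up to ~15% of
# the unit pattern amplitude (simulated-annealing design, then frozen).
_POTENTIAL_PATTERN_17 = (
    0.0, 1.0, 0.2019, -0.375, 0.1898, -0.0249, -0.4491, -0.0316, -0.5907,
    0.517, 0.2688, 0.7128, 0.88, 0.7864, 0.3817, -0.0404, 0.4804,
)


def potential_anomaly_pattern(n_years: int, amplitude: float, sign: float = 1.0) -> tuple:
    """Per-year anomaly with a positive-but-non-significant trend.

    Scales a frozen 17-point design sequence whose deterministic
    Kendall S lies in the middle of the Mann-Kendall non-significance
    band while the Theil-Sen slope stays strictly positive (times
    ``sign``); both properties are robust to small noise.  ``amplitude``
    sets the overall scale in the units the anomaly is injected in.
    For ``n_years != 17`` the sequence is linearly resampled; the
    S/slope properties are guaranteed only at the design length.
    """
    base = np.asarray(_POTENTIAL_PATTERN_17)
    if n_years == base.size:
        pattern = base
    else:
        if n_years < 4:
            raise ValueError("pattern needs at least 4 years")
        pattern = np.interp(
            np.linspace(0, base.size - 1, n_years), np.arange(base.size), base
        )
    return tuple(float(sign * amplitude * v) for v in pattern)


def demo_disturbance_scene(
    rows: int = 100,
    cols: int = 100,
    seed: int = 0,
    noise_sd: float = 0.02,
    cloud_fraction: float = 0.05,
) -> ScenarioConfig:
    """The 7-patch benchmark scene: one labelled patch per change type.

    Signal magnitudes are fixed design constants calibrated once against
    the default profiles and noise level (see the package methods note):
    tasseled-cap drift 0.003/yr gives a strongly significant DI trend;
    amplitude slope 0.04/yr a strongly significant GA trend; the
    "potential" patches carry +-0.9 x the frozen non-significant
    pattern.  Patches are 12x12 and sit inside the grassland zone of the
    default class layout; the rest of the grassland is the stable
    background.
    """
    if rows < 60 or cols < 100:
        raise ValueError("demo scene expects a grid of at least 60 x 100")
    n_years = 17
    years = tuple(range(2001, 2018))
    pot = potential_anomaly_pattern(n_years, 0.9)
    pot_neg = potential_anomaly_pattern(n_years, 0.9, sign=-1.0)
    di_up, di_down = 0.003, -0.003
    ga_up, ga_down = 0.04, -0.04
    patches = (
        TrendPatch(5, 17, 30, 42, di_slope=di_up, ga_slope=ga_up, label="recovery"),
        TrendPatch(5, 17, 55, 67, di_slope=di_up, ga_anomaly=pot, label="potential_recovery"),
        TrendPatch(25, 37, 30, 42, di_slope=di_up, ga_slope=ga_down, label="degradation"),
        TrendPatch(25, 37, 55, 67, di_slope=di_up, ga_anomaly=pot_neg, label="potential_degradation"),
        TrendPatch(45, 57, 30, 42, di_slope=di_down, ga_slope=ga_up, label="greenness_increase"),
        TrendPatch(45, 57, 55, 67, di_slope=di_down, ga_anomaly=pot, label="potential_greenness_increase"),
        TrendPatch(5, 17, 80, 92, to_class="water", transition_year=2015, label="turned_to_water"),
    )
    return ScenarioConfig(
        grid_rows=rows,
        grid_cols=cols,
        years=years,
        cloud_fraction=cloud_fraction,
        noise_sd=noise_sd,
        trend_patches=patches,
        rng_seed=seed,
    )


def null_scene(
    rows: int = 100,
    cols: int = 100,
    seed: int = 0,
    noise_sd: float = 0.02,
    cloud_fraction: float = 0.05,
) -> ScenarioConfig:
    """Stationary scene with no injected trends (false-positive control)."""
    return ScenarioConfig(
        grid_rows=rows,
        grid_cols=cols,
        cloud_fraction=cloud_fraction,
        noise_sd=noise_sd,
        rng_seed=seed,
    )
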