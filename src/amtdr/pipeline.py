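"""End-to-end orchestration: simulate -> preprocess -> features ->
classify -> trends -> rules -> assess.

:func:`run_pipeline` executes the whole workflow on a synthetic
scenario, holding the heavy arrays in memory (one year of daily data at
a time), writing stage outputs under an output directory and returning
a result bundle plus a manifest with per-stage record counts, timings
and array checksums.  Reruns with the same config and seed reproduce
identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import indices, landcover, preprocess, trend_stats
from .assessment import confusion_and_kappa
from .containers import CLASS_CODES
from .disturbance_rules import classify_map
from .raster_io import write_class_map, write_raster
from .synthetic_scene import ScenarioConfig, generate_stack, generate_training_points

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "features", "train", "predict", "trends", "disturb", "assess")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    scenario: ScenarioConfig
    output_dir: str | Path | None = None
    alpha: float = trend_stats.DEFAULT_ALPHA
    n_training_points: int = 3000
    pixel_area_km2: float = 0.25
    classifier: landcover.ClassifierConfig | None = None
    write_rasters: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PipelineResult:
    truth_map: np.ndarray
    training_points: pd.DataFrame
    standardization: indices.StandardizationStats
    annual_maps: dict
    model: landcover.TrainedModel
    di_annual: np.ndarray  # (n_years, rows, cols)
    ga_annual: np.ndarray
    di_trends: dict
    ga_trends: dict
    disturbance: np.ndarray
    fractions: pd.DataFrame
    area_table: pd.DataFrame
    confusion: object
    manifest: dict = field(default_factory=dict)


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full workflow on a synthetic scenario.

    Stage failures raise with the stage named; outputs written so far
    are left on disk for debugging.
    """
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seed": config.scenario.rng_seed, "alpha": config.alpha}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return manifest["stages"].setdefault(name, {})

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                manifest["stages"][name]["seconds"] = round(dt, 3)
                if exc_type is not None:
                    manifest["stages"][name]["failed"] = repr(exc)
                    log.error("stage %s failed after %.1fs", name, dt)
                    raise RuntimeError(f"pipeline stage {name!r} failed") from exc
                log.info("stage %s: done in %.1fs", name, dt)
                return False

        return _Ctx()

    scen = config.scenario
    seed_seq = np.random.SeedSequence(scen.rng_seed).spawn(3)
    years = list(scen.years)

    with stage("simulate") as m:
        stack, truth = generate_stack(scen)
        points = generate_training_points(
            truth,
            min(config.n_training_points, truth.size),
            seed=int(seed_seq[0].generate_state(1)[0] % 2**31),
        )
        m["n_epochs"] = int(stack.reflectance.shape[0])
        m["n_training_points"] = int(len(points))
        m["truth_checksum"] = _checksum(truth)
        if out_dir and config.write_rasters:
            write_class_map(out_dir / "truth_map.tif", truth)
            points.to_csv(out_dir / "training_points.csv", index=False)

    with stage("preprocess") as m:
        stack = preprocess.apply_qa_mask(stack)
        m["masked_fraction"] = float(np.mean(stack.qa))

    with stage("features") as m:
        coeffs = indices.load_tc_coefficients()
        # standardization reference: first-year growing-season TC of
        # vegetation-labelled training pixels (fallback: all valid pixels)
        daily0, valid0 = preprocess.interpolate_year(stack, years[0])
        tc0 = indices.compute_tasseled_cap(daily0, coeffs, band_axis=1)
        lo, hi = indices.GROWING_SEASON
        season = slice(lo - 1, hi)
        veg = points[points["class_name"].isin(["grassland", "forest"])]
        if len(veg) >= 2:
            ref = tc0[season][:, :, veg["row"].to_numpy(), veg["col"].to_numpy()]
            provenance = (
                f"year {years[0]} growing-season daily TC at {len(veg)} "
                "vegetation training pixels"
            )
        else:
            ref = tc0[season][:, :, valid0]
            provenance = f"year {years[0]} growing-season daily TC at all valid pixels"
        ref = np.moveaxis(ref, 1, -1).reshape(-1, 3)
        stats = indices.fit_standardization(ref, provenance=provenance)
        if out_dir:
            stats.save(out_dir / "standardization_stats.json")

        rows, cols = stack.grid_shape
        n_years = len(years)
        di_annual = np.full((n_years, rows, cols), np.nan)
        ga_annual = np.full((n_years, rows, cols), np.nan)
        feature_grids: dict[int, dict] = {}
        for yi, year in enumerate(years):
            if yi == 0:
                daily, valid = daily0, valid0
            else:
                daily, valid = preprocess.interpolate_year(stack, year)
            grids = indices.features_for_year(daily, stats, coeffs)
            grids["valid"] &= valid
            feature_grids[year] = grids
            di_annual[yi] = np.where(grids["valid"], grids["di"], np.nan)
            ga_annual[yi] = np.where(grids["valid"], grids["ga"], np.nan)
        del daily0, tc0, daily
        m["n_years"] = n_years
        m["di_checksum"] = _checksum(di_annual)
        m["ga_checksum"] = _checksum(ga_annual)

    with stage("train") as m:
        clf_cfg = config.classifier or landcover.ClassifierConfig(
            seed=int(seed_seq[1].generate_state(1)[0] % 2**31)
        )
        g0 = feature_grids[years[0]]
        pr, pc = points["row"].to_numpy(), points["col"].to_numpy()
        x = np.stack([g0[name][pr, pc] for name in indices.FEATURE_NAMES], axis=1)
        y = points["class_code"].to_numpy()
        ok = np.all(np.isfinite(x), axis=1) & g0["valid"][pr, pc]
        model = landcover.train(x[ok], y[ok], clf_cfg)
        m["n_train"] = int(ok.sum())
        m["holdout_accuracy"] = model.holdout_accuracy
        if out_dir:
            model.save(out_dir / "model.json")

    with stage("predict") as m:
        annual_maps = {
            year: landcover.predict_map(model, feature_grids[year], indices.FEATURE_NAMES)
            for year in years
        }
        m["map_checksums"] = {str(y): _checksum(annual_maps[y]) for y in years}
        if out_dir and config.write_rasters:
            for y in years:
                write_class_map(out_dir / f"classmap_{y}.tif", annual_maps[y])

    with stage("trends") as m:
        di_trends = trend_stats.trend_analysis(di_annual, np.array(years, float), config.alpha)
        ga_trends = trend_stats.trend_analysis(ga_annual, np.array(years, float), config.alpha)
        m["di_sig_fraction"] = float(np.nanmean(di_trends["significant"]))
        m["ga_sig_fraction"] = float(np.nanmean(ga_trends["significant"]))
        if out_dir and config.write_rasters:
            for var, tr in (("di", di_trends), ("ga", ga_trends)):
                write_raster(
                    out_dir / f"trend_{var}.tif",
                    np.stack([tr["sen_slope"], tr["z"], tr["p"], tr["significant"].astype(float)]),
                    band_names=["sen_slope", "mk_z", "p_value", "significant"],
                )

    with stage("disturb") as m:
        disturbance, fractions = classify_map(di_trends, ga_trends, annual_maps)
        m["n_disturbed"] = int(fractions.attrs["n_disturbed"])
        m["disturbed_fraction_pct"] = float(
            fractions.attrs["disturbed_fraction_of_grassland_pct"]
        )
        if out_dir and config.write_rasters:
            write_raster(out_dir / "disturbance.tif", disturbance, nodata=-1)
        if out_dir:
            fractions.to_csv(out_dir / "disturbance_fractions.csv", index=False)

    with stage("assess") as m:
        area_table = landcover.area_statistics(annual_maps, config.pixel_area_km2)
        first_map = annual_maps[years[0]]
        pr, pc = points["row"].to_numpy(), points["col"].to_numpy()
        sel = first_map[pr, pc] != 0
        confusion = confusion_and_kappa(
            points["class_code"].to_numpy()[sel], first_map[pr, pc][sel]
        )
        m["overall_accuracy_pct"] = confusion.overall_accuracy
        m["kappa"] = confusion.kappa
        if out_dir:
            area_table.to_csv(out_dir / "area_statistics.csv", index=False)
            confusion.to_frame().to_csv(out_dir / "confusion_matrix.csv")

    if out_dir:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(
        truth_map=truth,
        training_points=points,
        standardization=stats,
        annual_maps=annual_maps,
        model=model,
        di_annual=di_annual,
        ga_annual=ga_annual,
        di_trends=di_trends,
        ga_trends=ga_trends,
        disturbance=disturbance,
        fractions=fractions,
        area_table=area_table,
        confusion=confusion,
        manifest=manifest,
    )
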