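"""Generator contracts: determinism, physicality, template fidelity,
trend injection, samplers and drivers."""

import numpy as np
import pytest

from amtdr import indices, preprocess
from amtdr.containers import CLASS_CODES, epoch_doy
from amtdr.synthetic_scene import (
    DEFAULT_PROFILES,
    ScenarioConfig,
    TrendPatch,
    generate_climate,
    generate_dem,
    generate_livestock,
    generate_stack,
    generate_training_points,
    potential_anomaly_pattern,
    truth_class_map,
)
from amtdr.trend_stats import mann_kendall, sen_slope


class TestProfiles:
    def test_templates_physical_and_shaped(self):
        days = np.arange(1, 366)
        for name, prof in DEFAULT_PROFILES.items():
            t = prof.reflectance(days)
            assert np.all((t >= 0) & (t <= 1))
        water = DEFAULT_PROFILES["water"].reflectance(days)
        assert np.all(water[:, 1] < water[:, 0])  # NIR < red all year
        grass = DEFAULT_PROFILES["grassland"].reflectance(days)
        forest = DEFAULT_PROFILES["forest"].reflectance(days)
        nirv_g = indices.compute_nirv(grass[:, 0], grass[:, 1])
        nirv_f = indices.compute_nirv(forest[:, 0], forest[:, 1])
        assert nirv_f.max() > nirv_g.max()
        # single May-September peak for vegetation
        for nirv in (nirv_g, nirv_f):
            peak_day = int(np.argmax(nirv)) + 1
            assert 121 <= peak_day <= 273

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScenarioConfig(grid_rows=0, grid_cols=5)
        with pytest.raises(ValueError):
            ScenarioConfig(grid_rows=5, grid_cols=5, cloud_fraction=1.5)
        with pytest.raises(ValueError):
            ScenarioConfig(grid_rows=5, grid_cols=5, noise_sd=-0.1)
        with pytest.raises(ValueError):
            ScenarioConfig(
                grid_rows=5,
                grid_cols=5,
                trend_patches=(TrendPatch(0, 9, 0, 2),),
            )
        with pytest.raises(ValueError):  # overlap is contradictory
            ScenarioConfig(
                grid_rows=10,
                grid_cols=10,
                trend_patches=(
                    TrendPatch(0, 5, 0, 5, di_slope=0.01),
                    TrendPatch(3, 8, 3, 8, di_slope=-0.01),
                ),
            )


class TestGenerateStack:
    def test_zero_noise_identity_with_template(self, clean_scene):
        cfg, stack, truth = clean_scene
        doy = epoch_doy()
        for name, code in CLASS_CODES.items():
            sel = truth == code
            if not sel.any():
                continue
            r, c = np.argwhere(sel)[0]
            expected = DEFAULT_PROFILES[name].reflectance(doy)
            np.testing.assert_allclose(
                stack.reflectance[:, :, r, c], expected, atol=1e-6
            )

    def test_same_seed_bit_identical(self):
        cfg = ScenarioConfig(grid_rows=8, grid_cols=8, years=(2001, 2002), rng_seed=99)
        s1, t1 = generate_stack(cfg)
        s2, t2 = generate_stack(cfg)
        assert s1.reflectance.tobytes() == s2.reflectance.tobytes()
        assert s1.qa.tobytes() == s2.qa.tobytes()
        assert t1.tobytes() == t2.tobytes()

    def test_reflectance_physical_under_noise(self, small_scene):
        _, stack, _ = small_scene
        assert np.nanmin(stack.reflectance) >= 0.0
        assert np.nanmax(stack.reflectance) <= 1.0

    def test_di_drift_closed_form_recovery(self):
        """Zero-noise DI drift: the annual DI series recomputed by the
        indices module rises by the closed-form increment
        slope x (1/B_sd + 0.5/G_sd + 0.5/W_sd), and Theil-Sen recovers
        it within 1%."""
        slope = 0.002
        cfg = ScenarioConfig(
            grid_rows=8,
            grid_cols=8,
            years=tuple(range(2001, 2011)),
            cloud_fraction=0.0,
            noise_sd=0.0,
            rng_seed=1,
            trend_patches=(TrendPatch(0, 4, 0, 4, di_slope=slope),),
        )
        stack, truth = generate_stack(cfg)
        coeffs = indices.load_tc_coefficients()
        daily0, _ = preprocess.interpolate_year(stack, 2001)
        tc0 = indices.compute_tasseled_cap(daily0, coeffs, band_axis=1)
        lo, hi = indices.GROWING_SEASON
        veg = truth == CLASS_CODES["grassland"]
        ref = np.moveaxis(tc0[lo - 1 : hi][:, :, veg], 1, -1).reshape(-1, 3)
        stats = indices.fit_standardization(ref)
        di_years = []
        for year in cfg.years:
            daily, _ = preprocess.interpolate_year(stack, year)
            grids = indices.features_for_year(daily, stats, coeffs)
            di_years.append(grids["di"][1, 1])  # inside the patch
        di_years = np.array(di_years)
        increments = np.diff(di_years)
        expected = slope * (
            1.0 / stats.sd[0] + 0.5 / stats.sd[1] + 0.5 / stats.sd[2]
        )
        # float32 reflectance storage limits agreement to ~1e-5 relative
        np.testing.assert_allclose(increments, expected, rtol=1e-4)
        assert sen_slope(di_years) == pytest.approx(expected, rel=0.01)

    def test_di_drift_leaves_ga_untouched(self):
        """The DI injection is confined to non-red/NIR bands: GA of the
        drifted patch stays exactly equal to the background's."""
        cfg = ScenarioConfig(
            grid_rows=6,
            grid_cols=6,
            years=(2001, 2002, 2003, 2004),
            cloud_fraction=0.0,
            noise_sd=0.0,
            rng_seed=1,
            trend_patches=(TrendPatch(0, 3, 0, 3, di_slope=0.01),),
        )
        stack, truth = generate_stack(cfg)
        last = cfg.years[-1]
        daily, _ = preprocess.interpolate_year(stack, last)
        nirv = indices.compute_nirv(daily[:, 0], daily[:, 1])
        ga = indices.ga_for_grid(nirv)
        grass = truth == CLASS_CODES["grassland"]
        inside = grass.copy()
        inside[3:, :] = False
        inside[:, 3:] = False
        outside = grass & ~TrendPatch(0, 3, 0, 3).mask(6, 6)
        assert np.allclose(ga[inside], ga[outside].mean(), atol=1e-9)

    def test_ga_scaling_leaves_di_untouched(self):
        """The greening injection is TC-cancelled: DI of the greened
        patch equals the background's despite a big amplitude change."""
        cfg = ScenarioConfig(
            grid_rows=6,
            grid_cols=6,
            years=(2001, 2002, 2003),
            cloud_fraction=0.0,
            noise_sd=0.0,
            rng_seed=1,
            trend_patches=(TrendPatch(0, 3, 0, 3, ga_slope=0.2),),
        )
        stack, truth = generate_stack(cfg)
        coeffs = indices.load_tc_coefficients()
        last = cfg.years[-1]
        daily, _ = preprocess.interpolate_year(stack, last)
        tc = indices.compute_tasseled_cap(daily, coeffs, band_axis=1)
        grass = truth == CLASS_CODES["grassland"]
        patch = TrendPatch(0, 3, 0, 3).mask(6, 6)
        inside, outside = grass & patch, grass & ~patch
        lo, hi = indices.GROWING_SEASON
        season_tc = tc[lo - 1 : hi]
        np.testing.assert_allclose(
            season_tc[:, :, inside].mean(axis=-1),
            season_tc[:, :, outside].mean(axis=-1),
            atol=1e-6,  # float32 reflectance storage
        )
        # while GA genuinely moved
        nirv = indices.compute_nirv(daily[:, 0], daily[:, 1])
        ga = indices.ga_for_grid(nirv)
        assert ga[inside].mean() > ga[outside].mean() + 0.01

    def test_water_transition_truth_map(self):
        cfg = ScenarioConfig(
            grid_rows=6,
            grid_cols=6,
            years=tuple(range(2001, 2006)),
            trend_patches=(
                TrendPatch(0, 2, 0, 2, to_class="water", transition_year=2004),
            ),
        )
        before = truth_class_map(cfg, 2003)
        after = truth_class_map(cfg, 2004)
        assert np.all(before[0:2, 0:2] != CLASS_CODES["water"])
        assert np.all(after[0:2, 0:2] == CLASS_CODES["water"])


class TestTrainingPoints:
    def test_exhaustive_sample_returns_each_pixel_once(self):
        truth = np.full((10, 10), CLASS_CODES["grassland"], dtype=np.int16)
        truth[:3] = CLASS_CODES["forest"]
        pts = generate_training_points(truth, 100, seed=0)
        assert len(pts) == 100
        assert pts["pixel_id"].nunique() == 100

    def test_3000_unique_locations_on_200x200(self):
        from amtdr.synthetic_scene import default_class_map

        truth = default_class_map(200, 200)
        pts = generate_training_points(truth, 3000, seed=1)
        assert len(pts) == 3000
        assert pts["pixel_id"].nunique() == 3000

    def test_proportions_match_truth_within_binomial_error(self):
        from amtdr.synthetic_scene import default_class_map

        truth = default_class_map(200, 200)
        pts = generate_training_points(truth, 3000, seed=2)
        n = 3000
        for code in np.unique(truth):
            p_true = np.mean(truth == code)
            p_sample = np.mean(pts["class_code"] == code)
            se = np.sqrt(p_true * (1 - p_true) / n)
            # proportional stratification: tighter than binomial, but
            # binomial error is the documented bound
            assert abs(p_sample - p_true) < 3 * max(se, 1 / n)

    def test_oversampling_rejected(self):
        truth = np.full((5, 5), CLASS_CODES["grassland"], dtype=np.int16)
        with pytest.raises(ValueError):
            generate_training_points(truth, 26, seed=0)


class TestDrivers:
    def test_exact_target_correlation(self):
        rng = np.random.default_rng(0)
        di = rng.normal(size=17)
        for rho in (1.0, -1.0, 0.8, 0.0):
            counts = generate_livestock(di, rho, seed=1)
            r = np.corrcoef(di, counts)[0, 1]
            assert r == pytest.approx(rho, abs=1e-10)

    def test_correlation_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            generate_livestock(np.arange(5.0), 1.5)

    def test_climate_range_mapping(self):
        clim = generate_climate(
            range(2001, 2018), base=0.5, trend=0.05, noise_sd=0.3, seed=3,
            value_range=(-0.36, 1.79),
        )
        assert clim["value"].min() == pytest.approx(-0.36)
        assert clim["value"].max() == pytest.approx(1.79)
        assert np.all((clim["value"] >= -0.36) & (clim["value"] <= 1.79))

    def test_null_climate_mk_rejection_near_alpha(self):
        """Trend 0: Mann-Kendall should reject at about the alpha rate."""
        rejections = 0
        n_rep = 400
        for s in range(n_rep):
            clim = generate_climate(range(2001, 2018), base=0.0, trend=0.0, noise_sd=1.0, seed=s)
            if mann_kendall(clim["value"].to_numpy()).significant:
                rejections += 1
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.045) < 3 * se + 0.01

    def test_dem_spans_low_to_high_altitude(self):
        dem = generate_dem(50, 20, seed=0)
        assert dem.min() < 1000
        assert dem.max() > 6000


class TestPotentialPattern:
    def test_design_properties(self):
        pat = np.array(potential_anomaly_pattern(17, 1.0))
        res = mann_kendall(pat)
        assert 0 < res.mk_s < 50  # inside the non-significance band
        assert not res.significant
        assert res.sen_slope > 0
        neg = np.array(potential_anomaly_pattern(17, 1.0, sign=-1.0))
        assert mann_kendall(neg).mk_s == -res.mk_s
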