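"""NIRv, tasseled-cap, DI and GA identities and oracles."""

import numpy as np
import pytest

from amtdr import indices
from amtdr.indices import (
    FEATURE_NAMES,
    StandardizationStats,
    compute_di,
    compute_ga,
    compute_ndvi,
    compute_nirv,
    compute_tasseled_cap,
    fit_standardization,
    ga_for_grid,
    load_tc_coefficients,
    standardize_tc,
)


class TestNIRv:
    def test_definition_arithmetic(self):
        assert compute_ndvi(0.1, 0.3) == pytest.approx(0.5)
        assert compute_nirv(0.1, 0.3) == pytest.approx(0.15)

    def test_equal_bands_give_zero(self):
        assert compute_ndvi(0.2, 0.2) == 0.0
        assert compute_nirv(0.2, 0.2) == 0.0

    def test_zero_denominator_is_nodata_not_inf(self):
        out = compute_ndvi(np.array([0.0, 0.1]), np.array([0.0, 0.2]))
        assert np.isnan(out[0]) and np.isfinite(out[1])

    def test_identity_nirv_equals_ndvi_times_nir(self):
        rng = np.random.default_rng(0)
        red, nir = rng.random(100), rng.random(100)
        np.testing.assert_allclose(
            compute_nirv(red, nir), compute_ndvi(red, nir) * nir, rtol=0, atol=0
        )


class TestTasseledCap:
    def test_zero_reflectance_maps_to_origin(self):
        assert np.allclose(compute_tasseled_cap(np.zeros(7)), 0.0)

    def test_basis_vector_probes(self):
        coeffs = load_tc_coefficients()
        for k in range(7):
            e = np.zeros(7)
            e[k] = 1.0
            tc = compute_tasseled_cap(e, coeffs)
            assert tc[0] == pytest.approx(coeffs.brightness[k])
            assert tc[1] == pytest.approx(coeffs.greenness[k])
            assert tc[2] == pytest.approx(coeffs.wetness[k])

    def test_linearity(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x, y = rng.random(7), rng.random(7)
            a, b = rng.normal(size=2)
            lhs = compute_tasseled_cap(a * x + b * y)
            rhs = a * compute_tasseled_cap(x) + b * compute_tasseled_cap(y)
            np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_nan_band_propagates(self):
        x = np.full(7, 0.3)
        x[4] = np.nan
        assert np.all(np.isnan(compute_tasseled_cap(x)))


class TestStandardizationAndDI:
    def test_two_point_reference_stats(self):
        ref = np.array([[0.0, 1.0, 5.0], [2.0, 3.0, 7.0]])
        stats = fit_standardization(ref)
        assert stats.mean == pytest.approx((1.0, 2.0, 6.0))
        # sample SD with n-1 denominator
        assert stats.sd == pytest.approx((np.sqrt(2),) * 3)

    def test_self_standardization_zero_mean_unit_sd(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(200, 3))
        stats = fit_standardization(ref)
        z = standardize_tc(ref, stats)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_round_trip_persistence(self, tmp_path):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(50, 3))
        stats = fit_standardization(ref, provenance="test")
        stats.save(tmp_path / "stats.json")
        reloaded = StandardizationStats.load(tmp_path / "stats.json")
        x = rng.normal(size=(10, 3))
        np.testing.assert_array_equal(
            standardize_tc(x, stats), standardize_tc(x, reloaded)
        )

    def test_zero_variance_names_component(self):
        ref = np.column_stack([np.ones(5), np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError, match="brightness"):
            fit_standardization(ref)

    def test_di_at_origin_and_arithmetic(self):
        assert compute_di(np.zeros(3), standardized=True) == 0.0
        assert compute_di(np.array([1.5, -0.5, -0.5]), standardized=True) == pytest.approx(2.5)

    def test_di_monotone_in_disturbance_direction(self):
        """Brightness up with greenness/wetness down must raise DI."""
        rng = np.random.default_rng(4)
        ref = rng.normal(size=(100, 3))
        stats = fit_standardization(ref)
        base = rng.normal(size=3)
        for eps in (0.01, 0.1, 1.0):
            moved = base + eps * np.array([1.0, -1.0, -1.0])
            assert compute_di(moved, stats) > compute_di(base, stats)

    def test_di_invariant_under_affine_rescaling_with_refit(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(80, 3))
        x = rng.normal(size=(10, 3))
        di0 = compute_di(x, fit_standardization(ref))
        scale = np.array([2.0, 0.5, 10.0])
        shift = np.array([5.0, -1.0, 0.3])
        di1 = compute_di(x * scale + shift, fit_standardization(ref * scale + shift))
        np.testing.assert_allclose(di0, di1, atol=1e-9)


class TestGA:
    def test_constant_window(self):
        assert compute_ga(np.full(365, 0.4)) == pytest.approx(0.4)

    def test_linear_ramp_symmetric_mean(self):
        """Monotone ramp across the window: min at start, max at end,
        GA = mean of the whole window = midpoint."""
        v = np.zeros(365)
        lo, hi = indices.GROWING_SEASON
        n = hi - lo + 1
        v[lo - 1 : hi] = np.linspace(0.0, 1.0, n)
        assert compute_ga(v) == pytest.approx(0.5)

    def test_matches_brute_force_slice_mean(self):
        rng = np.random.default_rng(6)
        lo, hi = indices.GROWING_SEASON
        for _ in range(20):
            v = np.abs(
                np.sin(np.linspace(0, np.pi, 365)) * rng.uniform(0.1, 0.4)
                + rng.normal(0, 0.02, 365)
            )
            w = v[lo - 1 : hi]
            i_min, i_max = int(np.argmin(w)), int(np.argmax(w))
            a, b = sorted((i_min, i_max))
            expected = w[a : b + 1].mean()
            assert compute_ga(v) == pytest.approx(expected, abs=0)

    def test_order_agnostic_and_bounded(self):
        rng = np.random.default_rng(7)
        lo, hi = indices.GROWING_SEASON
        v = rng.random(365)
        ga = compute_ga(v)
        ga_rev = compute_ga(v[::-1].copy())  # reversed profile swaps min/max order
        w = v[lo - 1 : hi]
        assert w.min() <= ga <= w.max()
        wr = v[::-1][lo - 1 : hi]
        assert wr.min() <= ga_rev <= wr.max()

    def test_all_invalid_window_is_nodata(self):
        v = np.full(365, np.nan)
        assert np.isnan(compute_ga(v))

    def test_grid_vectorisation_matches_scalar(self):
        rng = np.random.default_rng(8)
        cube = rng.random((365, 4, 3))
        cube[:, 0, 0] = np.nan
        grid = ga_for_grid(cube)
        for r in range(4):
            for c in range(3):
                expected = compute_ga(cube[:, r, c])
                if np.isnan(expected):
                    assert np.isnan(grid[r, c])
                else:
                    assert grid[r, c] == pytest.approx(expected, abs=1e-12)


class TestFeatureRecords:
    def test_feature_vector_length_is_15(self):
        assert len(FEATURE_NAMES) == 15

    def test_noise_free_pixel_features_and_class_separation(self, clean_scene):
        from amtdr import preprocess
        from amtdr.containers import CLASS_CODES

        cfg, stack, truth = clean_scene
        daily, valid = preprocess.interpolate_year(stack, 2001)
        tc = compute_tasseled_cap(daily, band_axis=1)
        lo, hi = indices.GROWING_SEASON
        veg = (truth == CLASS_CODES["grassland"]) | (truth == CLASS_CODES["forest"])
        ref = np.moveaxis(tc[lo - 1 : hi][:, :, veg], 1, -1).reshape(-1, 3)
        stats = fit_standardization(ref)
        grids = indices.features_for_year(daily, stats)
        assert grids["valid"].all()
        # identical template pixels give identical features
        grass = truth == CLASS_CODES["grassland"]
        for name in FEATURE_NAMES:
            assert np.ptp(grids[name][grass]) == pytest.approx(0.0, abs=1e-9)
        # GA/DI centroids separate all four classes
        cents = {}
        for name, code in CLASS_CODES.items():
            m = truth == code
            cents[name] = (grids["ga"][m].mean(), grids["di"][m].mean())
        names = list(cents)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = np.array(cents[names[i]]), np.array(cents[names[j]])
                assert np.linalg.norm(a - b) > 0.05

    def test_ga_between_window_min_and_max(self, clean_scene):
        cfg, stack, truth = clean_scene
        from amtdr import preprocess

        daily, _ = preprocess.interpolate_year(stack, 2001)
        nirv = compute_nirv(daily[:, 0], daily[:, 1])
        lo, hi = indices.GROWING_SEASON
        w = nirv[lo - 1 : hi]
        ga = ga_for_grid(nirv)
        assert np.all(ga >= w.min(axis=0) - 1e-12)
        assert np.all(ga <= w.max(axis=0) + 1e-12)
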