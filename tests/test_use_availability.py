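import numpy as np
import pytest

from dogedge import (
    FitError,
    GridRaster,
    OccurrenceConfig,
    ZoneConfig,
    dog_density,
    extract_values_at_points,
    fit_avoidance,
    sample_available,
    simulate_occurrences,
    summarize_shift,
)
from dogedge.use_availability import avoidance_weight


class TestSampleAvailable:
    def test_zero_points(self):
        hab = GridRaster(np.ones((4, 4)), 0, 400, 100.0, "mask")
        assert len(sample_available(hab, 0, seed=1)) == 0

    def test_hundred_points_all_inside_habitat(self):
        rng = np.random.default_rng(41)
        vals = rng.integers(0, 2, (30, 30)).astype(float)
        hab = GridRaster(vals, 0, 3000, 100.0, "mask")
        pts = sample_available(hab, 100, seed=2)
        assert len(pts) == 100
        for x, y in pts.points:
            c = int(x // 100)
            r = int((3000 - y) // 100)
            assert vals[r, c] == 1

    def test_single_cell_uniformity(self):
        vals = np.zeros((5, 5))
        vals[2, 3] = 1.0
        hab = GridRaster(vals, 0, 500, 100.0, "mask")
        pts = sample_available(hab, 1000, seed=3)
        cx, cy = hab.cell_center(2, 3)
        se = 100.0 / np.sqrt(12.0) / np.sqrt(1000.0)
        assert abs(pts.points[:, 0].mean() - cx) < 3 * se
        assert abs(pts.points[:, 1].mean() - cy) < 3 * se

    def test_reproducible_and_seed_sensitive(self):
        hab = GridRaster(np.ones((10, 10)), 0, 1000, 100.0, "mask")
        a = sample_available(hab, 50, seed=7).points
        b = sample_available(hab, 50, seed=7).points
        c = sample_available(hab, 50, seed=8).points
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_empty_habitat_rejected(self):
        hab = GridRaster(np.zeros((3, 3)), 0, 300, 100.0, "mask")
        with pytest.raises(ValueError):
            sample_available(hab, 5, seed=1)


class TestSummarizeShift:
    def test_reserve_case_study_shift(self):
        """Availability mean 5.1 km vs use mean 12.4 km is a 7.3 km shift."""
        used = np.full(46, 12400.0)
        avail = np.array([5100.0 - 1000.0, 5100.0, 5100.0 + 1000.0] * 10)
        res = summarize_shift(used, avail)
        assert res.mean_used_km == pytest.approx(12.4)
        assert res.mean_avail_km == pytest.approx(5.1)
        assert res.shift_km == pytest.approx(7.3)
        assert round(res.shift_km) == 7

    def test_fraction_beyond_foray(self):
        """38 of 46 locations beyond 10.9 km gives 82.6% ~ 83%."""
        used = np.concatenate([np.full(38, 12000.0), np.full(8, 5000.0)])
        res = summarize_shift(used, np.full(10, 5000.0))
        assert res.frac_used_beyond_foray == pytest.approx(38 / 46)
        assert round(100 * res.frac_used_beyond_foray) == 83

    def test_identity_inputs(self):
        d = np.array([1000.0, 2000.0, 3000.0])
        res = summarize_shift(d, d)
        assert res.shift_km == 0.0
        assert res.shift_sd == 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        used = rng.uniform(0, 2e4, 30)
        avail = rng.uniform(0, 2e4, 50)
        a = summarize_shift(used, avail)
        b = summarize_shift(rng.permutation(used), rng.permutation(avail))
        assert b.n_used == a.n_used and b.n_available == a.n_available
        for field in ("mean_used_km", "mean_avail_km", "sd_avail_km",
                      "shift_km", "shift_sd", "frac_used_beyond_foray"):
            assert getattr(b, field) == pytest.approx(getattr(a, field), rel=1e-12)

    def test_frac_beyond_non_increasing_in_foray(self):
        rng = np.random.default_rng(6)
        used = rng.uniform(0, 2e4, 200)
        avail = rng.uniform(0, 2e4, 50)
        fracs = [
            summarize_shift(used, avail, ZoneConfig(0.0, f)).frac_used_beyond_foray
            for f in (2000.0, 6000.0, 10900.0, 15000.0)
        ]
        assert fracs == sorted(fracs, reverse=True)

    def test_zero_variance_availability(self):
        res = summarize_shift(np.array([2000.0]), np.full(5, 1000.0))
        assert res.shift_sd is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_shift(np.array([]), np.array([1.0]))


class TestFitAvoidance:
    def test_no_selection_limit_gives_flat_weight(self):
        rng = np.random.default_rng(51)
        avail = rng.uniform(0, 15000, 400)
        used = rng.uniform(0, 15000, 400)
        model = fit_avoidance(used, avail)
        pooled = np.concatenate([used, avail])
        flat = (model.theta_m < np.percentile(pooled, 5)) or (
            model.s_m > pooled.max() - pooled.min()
        )
        # either parameterization of "no avoidance": weight ratio across the
        # data range stays near 1
        lo_w = avoidance_weight(np.percentile(pooled, 5), model.theta_m, model.s_m)
        hi_w = avoidance_weight(np.percentile(pooled, 95), model.theta_m, model.s_m)
        assert flat or hi_w / lo_w < 2.0

    def test_recovers_foray_scale_threshold(self, default_landscape, default_surface):
        hits = 0
        for seed in range(10):
            occ = simulate_occurrences(
                default_surface, default_landscape.habitat,
                OccurrenceConfig(seed=seed, n_occurrences=500, scenario="many_dogs"),
            )
            used = extract_values_at_points(default_surface.raster, occ)
            avail = extract_values_at_points(
                default_surface.raster,
                sample_available(default_landscape.habitat, 2000, seed=900 + seed),
            )
            model = fit_avoidance(used, avail)
            hits += abs(model.theta_m - 10900.0) <= 1500.0
        assert hits >= 9

    def test_contrasting_scenario_recovers_low_threshold(self, default_landscape, default_surface):
        occ = simulate_occurrences(
            default_surface, default_landscape.habitat,
            OccurrenceConfig(seed=0, n_occurrences=500, scenario="few_dogs"),
        )
        used = extract_values_at_points(default_surface.raster, occ)
        avail = extract_values_at_points(
            default_surface.raster,
            sample_available(default_landscape.habitat, 2000, seed=901),
        )
        model = fit_avoidance(used, avail)
        assert model.theta_m < 5000.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(FitError):
            fit_avoidance(np.full(20, 5000.0), np.full(20, 5000.0))
        with pytest.raises(FitError):
            fit_avoidance(np.array([1.0]), np.full(20, 5000.0))


class TestDogDensity:
    @pytest.mark.parametrize(
        "n,area,expected",
        [(212, 479.0, 0.44), (42, 295.0, 0.14), (0, 100.0, 0.0)],
    )
    def test_reported_densities(self, n, area, expected):
        assert round(dog_density(n, area), 2) == pytest.approx(expected)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            dog_density(10, 0.0)


def test_null_draws_are_uncalibrated_shift(default_landscape, default_surface):
    """Used points drawn from availability itself show |shift| < 0.5 SD."""
    hab = default_landscape.habitat
    ok = 0
    n_trials = 50
    for t in range(n_trials):
        used = extract_values_at_points(
            default_surface.raster, sample_available(hab, 46, seed=3000 + 2 * t)
        )
        avail = extract_values_at_points(
            default_surface.raster, sample_available(hab, 100, seed=3001 + 2 * t)
        )
        res = summarize_shift(used[np.isfinite(used)], avail[np.isfinite(avail)])
        ok += abs(res.shift_sd) < 0.5
    assert ok / n_trials >= 0.95
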