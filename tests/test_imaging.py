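import numpy as np
import pytest

from swarmphage import (
    BiomassSeries,
    Calibration,
    ImageStack,
    biomass_timeseries,
    clearance_rate,
    clearance_rate_ratio,
    fit_quadratic_trend,
    phage_depth_profile,
    segment_fluorescence,
)
from swarmphage.synth import (
    BiofilmSceneParams,
    ColonySceneParams,
    _render_disc,
    gen_biofilm_zstack,
    gen_colony_timelapse,
)


def hourly_cal(pixel_size=1.0):
    return Calibration(pixel_size=pixel_size, frame_interval=3600.0)


class TestSegmentation:
    def test_disc_area_recovered_within_2pct(self):
        img = _render_disc(256, 50.0, fg=140.0, bg=10.0)
        _, area = segment_fluorescence(img, pixel_size=1.0)
        assert area == pytest.approx(np.pi * 50**2, rel=0.02)

    def test_background_only_fixed_threshold_gives_zero(self):
        img = np.full((64, 64), 10.0)
        _, area = segment_fluorescence(img, method="fixed", threshold=100.0)
        assert area == 0.0

    def test_constant_image_otsu_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate histogram"):
            segment_fluorescence(np.full((32, 32), 7.0))

    def test_area_monotone_in_fixed_threshold(self):
        rng = np.random.default_rng(0)
        img = _render_disc(128, 30.0, fg=140.0, bg=10.0) + rng.normal(0, 5, (128, 128))
        areas = [
            segment_fluorescence(img, method="fixed", threshold=thr, min_object_px=1)[1]
            for thr in np.linspace(0, 160, 17)
        ]
        assert all(b <= a for a, b in zip(areas, areas[1:]))

    def test_small_objects_despeckled(self):
        img = np.zeros((64, 64))
        img[10, 10] = 200.0  # single hot pixel
        img[30:40, 30:40] = 200.0  # 100-px object
        _, area = segment_fluorescence(img, method="fixed", threshold=100.0,
                                       min_object_px=9)
        assert area == 100.0

    def test_generated_frame_area_within_5pct_at_snr10(self):
        stack, truth, _ = gen_colony_timelapse(ColonySceneParams(seed=3))
        px = stack.calibration.pixel_size
        _, area = segment_fluorescence(stack.data[0], pixel_size=px)
        assert area == pytest.approx(truth.areas[0], rel=0.05)


class TestBiomassTimeseries:
    def test_constant_stack_gives_constant_series(self):
        frame = _render_disc(128, 30.0, fg=140.0, bg=10.0)
        stack = ImageStack(np.stack([frame] * 3), "time", hourly_cal())
        series = biomass_timeseries(stack)
        assert np.all(series.areas == series.areas[0])
        assert np.allclose(series.times, [0.0, 1.0, 2.0])

    def test_shrinking_discs_give_decreasing_areas(self):
        frames = [_render_disc(160, r, fg=140.0, bg=10.0) for r in (50.0, 40.0, 30.0)]
        series = biomass_timeseries(ImageStack(np.stack(frames), "time", hourly_cal()))
        assert np.all(np.diff(series.areas) < 0)
        for area, r in zip(series.areas, (50.0, 40.0, 30.0)):
            assert area == pytest.approx(np.pi * r**2, rel=0.02)

    def test_generated_timelapse_matches_truth_elementwise(self):
        stack, truth, _ = gen_colony_timelapse(ColonySceneParams(seed=2))
        series = biomass_timeseries(stack)
        assert np.allclose(series.areas, truth.areas, rtol=0.05)

    def test_requires_time_axis(self):
        stack, _, _ = gen_biofilm_zstack(BiofilmSceneParams(size_px=32, seed=0))
        with pytest.raises(ValueError, match="time"):
            biomass_timeseries(stack)


class TestQuadraticTrend:
    def test_noiseless_quadratic_recovered_exactly(self):
        t = np.arange(10.0)
        series = BiomassSeries(times=t, areas=100.0 - 2.0 * t - 0.5 * t * t)
        trend = fit_quadratic_trend(series)
        assert trend.coefficients == pytest.approx((100.0, -2.0, -0.5), abs=1e-9)
        assert np.allclose(trend.band_upper - trend.band_lower, 0.0, atol=1e-7)

    def test_constant_series_has_zero_slope_terms(self):
        t = np.arange(6.0)
        trend = fit_quadratic_trend(BiomassSeries(times=t, areas=np.full(6, 42.0)))
        assert trend.coefficients[1] == pytest.approx(0.0, abs=1e-9)
        assert trend.coefficients[2] == pytest.approx(0.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        series = BiomassSeries(times=np.arange(3.0), areas=np.ones(3))
        with pytest.raises(ValueError, match=">= 4"):
            fit_quadratic_trend(series)

    def test_band_covers_truth_95pct(self):
        # pointwise 95% CI of the mean should contain the noiseless curve
        # about 95% of the time across seeded replicates
        rng = np.random.default_rng(42)
        t = np.arange(10.0)
        truth = 100.0 - 2.0 * t - 0.3 * t * t
        hits = total = 0
        for _ in range(500):
            y = np.clip(truth + rng.normal(0, 5.0, t.size), 0.0, None)
            trend = fit_quadratic_trend(BiomassSeries(times=t, areas=y))
            hits += int(np.sum((trend.band_lower <= truth) & (truth <= trend.band_upper)))
            total += t.size
        assert 0.93 <= hits / total <= 0.97


class TestClearanceRate:
    def make_series(self, loss_fraction, hours=20, n=21):
        t = np.linspace(0, hours, n)
        return BiomassSeries(times=t, areas=1000.0 * (1 - loss_fraction * t / hours))

    def test_ten_fold_ratio_arithmetic(self):
        comparison = clearance_rate_ratio(self.make_series(0.5), self.make_series(0.05))
        assert comparison.ratio == pytest.approx(10.0, rel=1e-9)

    def test_identical_series_ratio_one(self):
        s = self.make_series(0.3)
        assert clearance_rate_ratio(s, s).ratio == pytest.approx(1.0)

    def test_nonpositive_control_rate_flagged(self):
        t = np.linspace(0, 20, 21)
        growing = BiomassSeries(times=t, areas=1000.0 + 10.0 * t)
        with pytest.warns(UserWarning, match="undefined"):
            comparison = clearance_rate_ratio(self.make_series(0.5), growing)
        assert not comparison.defined
        assert np.isnan(comparison.ratio)

    def test_quadratic_rate_matches_linear_decay(self):
        series = self.make_series(0.5)
        assert clearance_rate(series, method="quadratic") == pytest.approx(
            0.5 / 20.0, abs=1e-9
        )

    def test_generated_pair_recovers_10x_ratio(self):
        exp_stack, _, _ = gen_colony_timelapse(ColonySceneParams(a1=0.025, seed=0))
        ctl_stack, _, _ = gen_colony_timelapse(ColonySceneParams(a1=0.0025, seed=100))
        comparison = clearance_rate_ratio(
            biomass_timeseries(exp_stack), biomass_timeseries(ctl_stack)
        )
        assert comparison.ratio == pytest.approx(10.0, rel=0.15)


class TestDepthProfile:
    def test_gaussian_law_peak_recovered_within_one_slice(self):
        stack, truth, _ = gen_biofilm_zstack(BiofilmSceneParams(seed=0))
        profile = phage_depth_profile(stack)
        assert abs(profile.peak_z - 50.0) <= stack.calibration.z_step

    def test_surface_spots_peak_at_top(self):
        # control-like geometry: phages only near the surface
        stack, _, _ = gen_biofilm_zstack(
            BiofilmSceneParams(depth_law="surface_exponential", seed=1)
        )
        assert phage_depth_profile(stack).peak_z == 0.0

    def test_empty_stack_is_an_error(self):
        with pytest.raises(ValueError):
            stack, _, _ = gen_biofilm_zstack(
                BiofilmSceneParams(spots_at_peak=0.0, noise_sd=0.0, seed=0)
            )
            phage_depth_profile(stack)

    def test_coverage_invariant_to_intensity_rescaling(self):
        stack, _, _ = gen_biofilm_zstack(BiofilmSceneParams(size_px=128, seed=2))
        scaled = ImageStack(stack.data * 2.5, "depth", stack.calibration)
        p1 = phage_depth_profile(stack)
        p2 = phage_depth_profile(scaled)
        assert np.allclose(p1.coverage, p2.coverage, atol=1e-3)
        assert p1.peak_z == p2.peak_z

    def test_coverage_bounded_and_complete(self):
        stack, _, _ = gen_biofilm_zstack(BiofilmSceneParams(size_px=64, seed=3))
        profile = phage_depth_profile(stack)
        assert len(profile.z) == stack.n_planes
        assert np.all((0 <= profile.coverage) & (profile.coverage <= 1))
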