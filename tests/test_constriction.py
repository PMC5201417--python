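"""Myosin preprocessing, event detection, and constriction timing."""

import numpy as np
import pytest
from scipy.stats import norm

import furrowkit as fk
from furrowkit.constriction import CellTrace, HalfTimeResult, MyosinStack


def make_cell(times_min, area, myosin, cell_id="c0"):
    return CellTrace(cell_id=cell_id, times=np.asarray(times_min, float),
                     apical_area=np.asarray(area, float),
                     myosin_intensity=np.asarray(myosin, float))


class TestStackPreprocessing:
    def test_all_subthreshold_gives_zero_projection(self):
        stack = MyosinStack(data=np.ones((3, 4, 4)), cyto_mean=5.0,
                            cyto_sd=1.0)
        proj = fk.preprocess_myosin_stack(stack, smoothing_sigma=0.0)
        assert np.all(proj == 0.0)

    def test_top_two_rule_single_qualifier(self):
        data = np.zeros((3, 1, 1))
        data[:, 0, 0] = [10.0, 3.0, 2.0]
        stack = MyosinStack(data=data, cyto_mean=2.5, cyto_sd=1.0)
        proj = fk.preprocess_myosin_stack(stack, smoothing_sigma=0.0)
        assert proj[0, 0] == pytest.approx(10.0)

    def test_nonzero_exactly_where_top_two_exceed_threshold(self, rng):
        data = rng.uniform(0, 10, size=(5, 8, 8))
        threshold = 7.0  # mean 4.5 + 2.5 * sd 1.0
        stack = MyosinStack(data=data, cyto_mean=4.5, cyto_sd=1.0)
        proj = fk.preprocess_myosin_stack(stack, smoothing_sigma=0.0)
        top2 = np.sort(data, axis=0)[-2:]
        expected_nonzero = (top2 > threshold).any(axis=0)
        np.testing.assert_array_equal(proj > 0, expected_nonzero)
        # kept value is the max of the qualifying top-two values
        np.testing.assert_allclose(
            proj[expected_nonzero],
            np.where(top2 > threshold, top2, 0).max(axis=0)[expected_nonzero])

    def test_missing_cytoplasmic_stats_rejected(self):
        stack = MyosinStack(data=np.ones((3, 4, 4)))
        with pytest.raises(ValueError, match="cytoplasmic"):
            fk.preprocess_myosin_stack(stack)

    def test_background_region_estimation(self):
        data = np.ones((3, 6, 6))
        data[:, :2, :2] = 2.0  # background patch with zero variance
        stack = MyosinStack(data=data)
        proj = fk.preprocess_myosin_stack(
            stack, background_region=(slice(0, 2), slice(0, 2)),
            smoothing_sigma=0.0)
        # threshold = 2.0; nothing exceeds it
        assert np.all(proj == 0.0)


class TestSmoothingAndRates:
    def test_constant_series_unchanged(self):
        x = np.full(20, 3.7)
        np.testing.assert_allclose(fk.smooth_trace(x, 2.0), x, atol=1e-12)

    def test_sum_preserved_with_reflective_boundaries(self, rng):
        x = rng.normal(size=50)
        assert fk.smooth_trace(x, 3.0).sum() == pytest.approx(x.sum(),
                                                              abs=1e-9)

    def test_smoothing_commutes_with_additive_constant(self, rng):
        x = rng.normal(size=30)
        np.testing.assert_allclose(fk.smooth_trace(x + 5.0, 2.0),
                                   fk.smooth_trace(x, 2.0) + 5.0, atol=1e-12)

    def test_linear_area_loss_constant_constriction_rate(self):
        t = np.arange(0, 30, 0.5)
        cell = make_cell(t, 80.0 - 2.0 * t, np.full(t.size, 7.0))
        area_rate, myo_rate = fk.instantaneous_rates(cell)
        # reflective boundaries flatten the ramp near the edges; the rate
        # is exactly 2 beyond the kernel radius (4 sigma + 1 frames)
        interior = slice(9, -9)
        np.testing.assert_allclose(area_rate[interior], 2.0, atol=1e-9)
        np.testing.assert_allclose(myo_rate, 0.0, atol=1e-9)

    def test_quadratic_series_central_difference_exact(self):
        # central differences are exact for quadratics at interior points
        t = np.arange(0, 10, 0.5)
        cell = make_cell(t, 100.0 - t ** 2, t ** 2)
        area_rate, myo_rate = fk.instantaneous_rates(cell, sigma=0.0)
        np.testing.assert_allclose(area_rate[1:-1], 2 * t[1:-1], atol=1e-9)
        np.testing.assert_allclose(myo_rate[1:-1], 2 * t[1:-1], atol=1e-9)

    def test_rates_invariant_to_trace_shift(self, rng):
        t = np.arange(0, 10, 0.5)
        myo = rng.uniform(50, 150, t.size)
        a = make_cell(t, np.full(t.size, 40.0), myo)
        b = make_cell(t, np.full(t.size, 40.0) + 11.0, myo + 23.0)
        ra = fk.instantaneous_rates(a)
        rb = fk.instantaneous_rates(b)
        np.testing.assert_allclose(ra[0], rb[0], atol=1e-9)
        np.testing.assert_allclose(ra[1], rb[1], atol=1e-9)


class TestControlStatsAndEvents:
    def embryo_from_slopes(self, slopes, genotype="ctrl"):
        t = np.arange(0, 10, 0.5)
        cells = [make_cell(t, np.full(t.size, 40.0), 100.0 + s * t,
                           cell_id=f"c{i}")
                 for i, s in enumerate(slopes)]
        return fk.EmbryoDataset(embryo_id="e0", genotype=genotype,
                                cells=cells, frame_interval=30.0)

    def test_pooled_mean_over_constant_slope_cells(self):
        emb = self.embryo_from_slopes([0.0, 2.0])
        stats = fk.control_rate_stats([emb], sigma=0.0)
        assert stats.mean_rate == pytest.approx(1.0, abs=1e-9)
        assert stats.n_points == 2 * 20

    def test_pooling_is_order_invariant(self):
        a = self.embryo_from_slopes([0.0, 1.0])
        b = self.embryo_from_slopes([3.0])
        s_ab = fk.control_rate_stats([a, b])
        s_ba = fk.control_rate_stats([b, a])
        assert s_ab.mean_rate == pytest.approx(s_ba.mean_rate)
        assert s_ab.sd_rate == pytest.approx(s_ba.sd_rate)

    def test_band_membership_boundaries(self):
        stats = fk.ControlRateStats(mean_rate=10.0, sd_rate=2.0, n_points=100,
                                    source_genotype="ctrl")
        rates = {"c": np.array([10.0, 13.0, 15.0, 12.0, 14.0, 9.0])}
        ev = fk.detect_accumulation_events(rates, stats, lo=1.0, hi=2.0)
        flagged = {i for _, i in ev.instances}
        # 13 = mean + 1.5 sd flagged; 12 and 14 sit exactly on the closed
        # interval boundaries; 15 = mean + 2.5 sd excluded
        assert flagged == {1, 3, 4}

    def test_no_events_when_all_at_mean(self):
        stats = fk.ControlRateStats(10.0, 2.0, 100, "ctrl")
        ev = fk.detect_accumulation_events({"c": np.full(50, 10.0)}, stats)
        assert len(ev) == 0

    def test_zero_sd_rejected(self):
        stats = fk.ControlRateStats(10.0, 0.0, 100, "ctrl")
        with pytest.raises(ValueError):
            fk.detect_accumulation_events({"c": np.zeros(5)}, stats)

    def test_gaussian_calibration_of_flagged_fraction(self):
        rng = np.random.default_rng(99)
        rates = rng.normal(5.0, 2.0, size=100_000)
        stats = fk.ControlRateStats(mean_rate=float(rates.mean()),
                                    sd_rate=float(rates.std(ddof=1)),
                                    n_points=rates.size,
                                    source_genotype="ctrl")
        ev = fk.detect_accumulation_events({"c": rates}, stats)
        expected = norm.cdf(2) - norm.cdf(1)
        assert len(ev) / rates.size == pytest.approx(expected, abs=0.005)

    def test_rates_at_events_and_error_paths(self):
        ev = fk.EventSet(instances=[("c", 2)], lo_sd=1, hi_sd=2)
        rates = fk.constriction_rates_at_events({"c": np.array([0., 1., 3.])},
                                                ev)
        np.testing.assert_allclose(rates, [3.0])
        with pytest.raises(KeyError):
            fk.constriction_rates_at_events({"other": np.zeros(3)}, ev)
        with pytest.warns(UserWarning, match="empty"):
            out = fk.constriction_rates_at_events(
                {"c": np.zeros(3)},
                fk.EventSet(instances=[], lo_sd=1, hi_sd=2))
        assert out.size == 0


class TestAlignmentAndHalfTime:
    def area_embryo(self, onset_min, embryo_id="e", n_cells=3, total_min=20.0,
                    rate=3.0):
        t = np.arange(0, total_min, 1 / 12)  # 5 s frames
        area = np.where(t < onset_min, 40.0, 40.0 - rate * (t - onset_min))
        area = np.maximum(area, 2.0)
        cells = [make_cell(t, area, np.full(t.size, 100.0), f"c{i}")
                 for i in range(n_cells)]
        return fk.EmbryoDataset(embryo_id=embryo_id, genotype="g",
                                cells=cells, frame_interval=5.0)

    def test_shifted_embryos_get_shifted_offsets(self):
        a = self.area_embryo(onset_min=2.0, embryo_id="a")
        b = self.area_embryo(onset_min=3.0, embryo_id="b")
        fk.align_embryos([a, b])
        assert not a.unalignable and not b.unalignable
        assert b.alignment_offset - a.alignment_offset == pytest.approx(
            1.0, abs=2 / 12)

    def test_flat_embryo_flagged_unalignable(self):
        t = np.arange(0, 10, 1 / 12)
        cells = [make_cell(t, np.full(t.size, 40.0), np.full(t.size, 100.0))]
        emb = fk.EmbryoDataset("flat", "g", cells, frame_interval=5.0)
        fk.align_embryos([emb])
        assert emb.unalignable
        assert emb.alignment_offset is None

    def test_onset_detected_within_two_frames(self):
        emb = self.area_embryo(onset_min=4.0)
        fk.align_embryos([emb])
        assert abs(emb.alignment_offset - 4.0) <= 2 * (5.0 / 60.0) + 1e-9

    def test_linear_decay_half_time(self):
        # losing 10% of A0 per minute reaches 50% in 5 minutes
        t = np.arange(0, 10, 0.1)
        area = 40.0 * (1 - 0.1 * t)
        res = fk.time_to_half_area(area, t, onset_time=0.0)
        assert res.a0 == pytest.approx(40.0)
        assert res.half_time == pytest.approx(5.0, abs=1e-9)

    def test_exponential_decay_half_time(self):
        t = np.arange(0, 30, 0.05)
        area = 40.0 * np.exp(-t / 10.0)
        res = fk.time_to_half_area(area, t, onset_time=0.0)
        assert res.half_time == pytest.approx(10 * np.log(2), abs=0.01)

    def test_invariant_to_uniform_area_rescaling(self):
        t = np.arange(0, 20, 0.1)
        area = 40.0 - 1.5 * t
        r1 = fk.time_to_half_area(np.maximum(area, 1.0), t)
        r2 = fk.time_to_half_area(np.maximum(area, 1.0) * 3.0, t)
        assert r1.half_time == pytest.approx(r2.half_time, abs=1e-9)

    def test_never_crossing_is_censored(self):
        t = np.arange(0, 5, 0.1)
        res = fk.time_to_half_area(40.0 - 0.5 * t, t)
        assert res.censored
        assert np.isnan(res.half_time)


class TestIntensityProfilePair:
    def test_identical_images_identical_profiles(self, rng):
        img = rng.uniform(0, 100, size=(3, 20, 120))
        pa, pb = fk.intensity_profile_pair(img, img.copy(), pixel_size=0.5)
        np.testing.assert_allclose(pa, pb)
        assert pa.size == int(round(33.0 / 0.5))

    def test_scaled_image_scales_profile(self, rng):
        img = rng.uniform(0, 100, size=(3, 20, 120))
        pa, pb = fk.intensity_profile_pair(img, 0.5 * img, pixel_size=0.5)
        np.testing.assert_allclose(pb, 0.5 * pa, rtol=1e-12)

    def test_peak_time_selected_from_time_series(self, rng):
        base = rng.uniform(0, 10, size=(3, 10, 80))
        movie = np.stack([base, 5 * base, 2 * base])  # peak at frame 1
        pa, pb = fk.intensity_profile_pair(movie, movie, pixel_size=0.5)
        ref, _ = fk.intensity_profile_pair(5 * base, 5 * base, pixel_size=0.5)
        np.testing.assert_allclose(pa, ref)
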