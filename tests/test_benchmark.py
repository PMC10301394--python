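"""Statistical, frequency-ratio and template-based benchmark SQIs."""

import numpy as np
import pytest

import ppgsqi as p
from ppgsqi.benchmark import (
    PsdEstimate,
    band_power,
    cardio_sqi,
    extract_templates,
    freq_sqis,
    stat_sqis,
    template_sqis,
    welch_psd,
)

FS = 250.0


class TestStatSqis:
    def test_single_cosine_cycle_crosses_twice(self):
        t = np.arange(int(FS)) / FS
        out = stat_sqis(np.cos(2 * np.pi * t) + 5.0, FS)  # DC removed internally
        assert out["zcSQI"] == 2

    def test_gaussian_moments(self):
        x = np.random.default_rng(0).standard_normal(200_000)
        out = stat_sqis(x, FS)
        assert abs(out["sSQI"]) < 0.02
        assert out["kSQI"] == pytest.approx(3.0, abs=0.05)  # Pearson convention
        assert out["elgSQI"] == pytest.approx(1 - 2 / np.pi, abs=0.01)

    def test_autocorrelation_peak_at_signal_period(self, clean_epoch):
        out = stat_sqis(clean_epoch.samples, FS)
        assert out["ACPeak1"] > 0.5
        assert out["ACPeak1"] >= out["ACPeak2"] - 0.25

    def test_constant_epoch_flags_missing(self):
        out = stat_sqis(np.full(2000, 3.0), FS)
        assert out["zcSQI"] == 0
        for name in ("sSQI", "kSQI", "elgSQI", "ACPeak1", "ACPeak2"):
            assert np.isnan(out[name])

    def test_scale_and_offset_invariance(self, clean_epoch):
        a = stat_sqis(clean_epoch.samples, FS)
        b = stat_sqis(4.2 * clean_epoch.samples + 11.0, FS)
        for name in ("zcSQI", "sSQI", "kSQI", "elgSQI", "ACPeak1"):
            assert a[name] == pytest.approx(b[name], rel=1e-9)


class TestWelchAndFreqSqis:
    def test_tone_psd_peaks_at_tone(self):
        t = np.arange(2000) / FS
        psd = welch_psd(np.sin(2 * np.pi * 1.2 * t), FS)
        assert psd.freqs_hz[np.argmax(psd.power)] == pytest.approx(1.2, abs=0.3)

    def test_parseval_total_power_matches_variance(self):
        x = np.random.default_rng(3).standard_normal(2000)
        psd = welch_psd(x, FS)
        df = psd.freqs_hz[1] - psd.freqs_hz[0]
        total = np.sum(psd.power) * df
        assert total == pytest.approx(np.var(x), rel=0.05)

    def _psd_with_power_in(self, lo, hi):
        freqs = np.linspace(0, 125, 1001)
        power = np.where((freqs >= lo) & (freqs < hi), 1.0, 0.0)
        return PsdEstimate(freqs, power, FS, 2.0, 0.5, "hamming")

    def test_all_power_in_cardiac_band(self):
        out = freq_sqis(self._psd_with_power_in(1.0, 2.25))
        assert out["RelP"] == pytest.approx(1.0)
        assert out["fSNR_no_DC"] == pytest.approx(1.0)
        assert out["fSNR"] == pytest.approx(1.0)

    def test_all_power_below_one_hz(self):
        out = freq_sqis(self._psd_with_power_in(0.0, 1.0))
        assert out["iorSQI"] == 0.0
        assert np.isnan(out["RelP"])  # zero denominator flagged

    def test_ratio_ranges_on_random_psd(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            psd = PsdEstimate(
                np.linspace(0, 125, 400), rng.random(400), FS, 2.0, 0.5, "hamming"
            )
            out = freq_sqis(psd)
            for name in ("RelP", "fSNR", "iorSQI_no_DC", "fSNR_no_DC"):
                assert 0.0 <= out[name] <= 1.0
            assert out["iorSQI"] >= 0.0

    def test_band_power_is_amplitude_squared_scaled(self):
        psd = self._psd_with_power_in(1.0, 8.0)
        assert band_power(psd, 1.0, 8.0) > 0
        assert band_power(psd, 10.0, 20.0) == 0.0


class TestMmaDetector:
    def test_pure_sine_peaks_at_maxima(self):
        t = np.arange(2000) / FS
        peaks = p.mma_detect_peaks(np.sin(2 * np.pi * 1.0 * t), FS)
        assert len(peaks) == 8
        # maxima of sin at t = 0.25 + k
        expected = (0.25 + np.arange(8)) * FS
        assert np.all(np.abs(peaks - expected) <= 0.02 * FS)

    def test_constant_signal_has_no_peaks(self):
        assert len(p.mma_detect_peaks(np.ones(2000), FS)) == 0

    def test_clean_ppg_epoch_beat_count_and_intervals(self):
        record = p.synthesize_record("s", "green", 32, hr_profile=1.2, seed=6)
        filtered = p.attenuate_breathing(record)
        epoch = p.epoch_record(filtered)[2]
        peaks = p.mma_detect_peaks(epoch.samples, FS)
        assert len(peaks) in (9, 10, 11)  # ~9.6 beats in 8 s at 1.2 Hz
        intervals = np.diff(peaks) / FS
        assert np.all(np.abs(intervals - 1 / 1.2) < 0.1 / 1.2)

    def test_epoch_too_short_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            p.mma_detect_peaks(np.ones(100), FS)


class TestTemplates:
    def test_half_width_is_half_median_interval(self):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 1.25 * t)
        peaks = np.arange(50, 2000, 200)  # every 0.8 s
        seg = extract_templates(x, FS, peaks)
        assert len(seg.templates[0]) == pytest.approx(0.8 * FS, abs=1)

    def test_edge_truncated_beats_dropped(self):
        x = np.random.default_rng(7).standard_normal(2000)
        peaks = np.array([25, 225, 425, 625, 825])  # first: 0.1 s from edge
        seg = extract_templates(x, FS, peaks)  # half-width 100 samples (0.4 s)
        assert len(seg.templates) == 4

    def test_interior_peaks_mostly_retained(self):
        peaks = np.arange(100, 1900, 200)  # 9 interior peaks
        x = np.random.default_rng(8).standard_normal(2000)
        seg = extract_templates(x, FS, peaks)
        assert len(seg.templates) >= 7

    def test_fewer_than_two_peaks_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            extract_templates(np.ones(2000), FS, np.array([500]))

    def test_identical_templates_reduce_to_per_beat_value(self):
        bt = p.make_beat_template(1.25)
        x = np.tile(bt.samples, 10)
        peaks = np.argmax(bt.samples) + len(bt.samples) * np.arange(10)
        seg = extract_templates(x, FS, peaks)
        out = template_sqis(seg, FS)
        single = template_sqis(
            p.benchmark.BeatSegmentation(peaks[:2], seg.templates[:2], 0.4), FS
        )
        for name in out:
            assert out[name] == pytest.approx(single[name], rel=1e-9)

    def test_symmetric_triangle_has_zero_skew(self):
        tri = np.concatenate([np.linspace(0, 1, 100), np.linspace(1, 0, 100)])
        seg = p.benchmark.BeatSegmentation(np.array([100, 300]), [tri, tri], 0.4)
        out = template_sqis(seg, FS)
        assert out["beatSSQI"] == pytest.approx(0.0, abs=1e-9)


class TestCardioSqi:
    def test_pure_sine_two_extrema_per_peak(self):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        peaks = p.mma_detect_peaks(x, FS)
        assert cardio_sqi(x, peaks) == pytest.approx(2.0, abs=0.3)

    def test_white_noise_far_above_clean(self, clean_epoch):
        rng = np.random.default_rng(9)
        noise = rng.standard_normal(2000)
        clean_ratio = cardio_sqi(
            clean_epoch.samples, p.mma_detect_peaks(clean_epoch.samples, FS)
        )
        noisy_ratio = cardio_sqi(noise, p.mma_detect_peaks(noise, FS))
        assert noisy_ratio > 3 * clean_ratio


class TestAssembly:
    def test_clean_epoch_all_entries_finite(self, clean_epoch):
        out = p.compute_all_sqis(clean_epoch)
        assert set(out) == set(p.SQI_NAMES)
        assert all(np.isfinite(v) for v in out.values())

    def test_flat_line_epoch_flags_missing_without_crash(self, clean_epoch):
        flat = p.Epoch(
            "s", "green", 0.0, FS, np.full(2000, 2.0), "clean", (1.0, 0.0, 0.0)
        )
        out = p.compute_all_sqis(flat)
        assert np.isnan(out["sSQI"]) and np.isnan(out["MedRelP"])

    def test_feature_table_row_per_epoch(self, cohort_epochs, features):
        assert len(features) == len(cohort_epochs)
        assert set(p.SQI_NAMES) <= set(features.columns)

    def test_direction_of_benchmarks_on_cohort(self, binary_features):
        """Noise raises zero-crossings and zero-gradient counts; clean
        signals are more self-correlated with more cardiac-band power."""
        b = binary_features
        clean, noisy = b[b.label == "clean"], b[b.label == "noisy"]
        assert noisy["zcSQI"].mean() > clean["zcSQI"].mean()
        assert noisy["cardioSQI"].mean() > clean["cardioSQI"].mean()
        assert clean["ACPeak1"].mean() > noisy["ACPeak1"].mean()
        assert clean["RelP"].mean() > noisy["RelP"].mean()
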