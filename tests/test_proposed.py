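"""Fundamental-lobe localization, band selection and shape descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ppgsqi as p
from ppgsqi.modspec import AggregatedModSpectrum
from ppgsqi.proposed import (
    DegenerateSpectrumError,
    detect_harmonic,
    find_fundamental,
    select_band,
    spectral_centroid,
    spectral_crest,
    spectral_entropy,
    spectral_spread,
)


def make_agg(power, f_lo=0.0, f_hi=4.0):
    power = np.asarray(power, dtype=float)
    freqs = np.linspace(f_lo, f_hi, len(power))
    return AggregatedModSpectrum(power, freqs, (2.0, 8.0))


def full_band(agg):
    """LobeBand covering the whole aggregated axis (closed-form tests)."""
    return p.LobeBand(
        fmain_hz=1.0,
        harmonic_found=False,
        band_hz=(agg.mod_freqs_hz[0], agg.mod_freqs_hz[-1]),
        bin_range=(0, len(agg.power) - 1),
    )


class TestFindFundamental:
    def test_delta_spectrum(self):
        freqs = np.linspace(0, 4, 401)
        power = np.zeros(401)
        power[np.argmin(np.abs(freqs - 1.2))] = 5.0
        agg = AggregatedModSpectrum(power, freqs, (2, 8))
        assert find_fundamental(agg) == pytest.approx(1.2, abs=0.01)

    def test_tie_breaks_to_lower_frequency(self):
        freqs = np.linspace(0, 4, 401)
        power = np.zeros(401)
        power[np.argmin(np.abs(freqs - 1.0))] = 5.0
        power[np.argmin(np.abs(freqs - 2.0))] = 5.0
        agg = AggregatedModSpectrum(power, freqs, (2, 8))
        assert find_fundamental(agg) == pytest.approx(1.0, abs=0.01)

    def test_all_zero_band_is_degenerate(self):
        agg = make_agg(np.zeros(100))
        with pytest.raises(DegenerateSpectrumError):
            find_fundamental(agg)


class TestDetectHarmonic:
    def _two_peak(self, f1=1.2, f2=2.4, h2=0.5):
        freqs = np.linspace(0, 4, 801)
        power = np.exp(-0.5 * ((freqs - f1) / 0.05) ** 2)
        power = power + h2 * np.exp(-0.5 * ((freqs - f2) / 0.05) ** 2)
        return AggregatedModSpectrum(power, freqs, (2, 8))

    def test_half_height_harmonic_detected(self):
        agg = self._two_peak()
        assert detect_harmonic(agg, 1.2) is True

    def test_harmonic_outside_search_range(self):
        agg = self._two_peak()
        assert detect_harmonic(agg, 2.0) is False  # 2*fmain = 4.0 > 3.6

    def test_single_peak_spectrum_has_no_harmonic(self):
        freqs = np.linspace(0, 4, 801)
        power = np.exp(-0.5 * ((freqs - 1.2) / 0.05) ** 2) + 1e-6
        agg = AggregatedModSpectrum(power, freqs, (2, 8))
        assert detect_harmonic(agg, 1.2) is False

    def test_literal_rule_requires_high_fundamental(self):
        agg = self._two_peak()
        assert detect_harmonic(agg, 1.2, rule="literal") is False


class TestSelectBand:
    @pytest.mark.parametrize(
        "fmain,harmonic,expected",
        [(1.2, True, (0.8, 1.8)), (1.2, False, (0.8, 3.6)), (0.8, True, (0.8, 1.2))],
    )
    def test_band_edges(self, fmain, harmonic, expected):
        freqs = np.linspace(0, 4, 801)
        band = select_band(fmain, harmonic, freqs)
        assert band.band_hz == pytest.approx(expected)
        lo, hi = band.bin_range
        assert freqs[lo] >= expected[0] and freqs[hi] <= expected[1]
        assert freqs[lo - 1] < expected[0] and freqs[hi + 1] > expected[1]

    def test_too_coarse_axis_rejected(self):
        freqs = np.linspace(0, 4, 9)  # 0.5 Hz bins: (0.8, 1.2) holds one bin
        with pytest.raises(ValueError, match="modulation"):
            select_band(0.8, True, freqs)


class TestDescriptorClosedForms:
    def test_entropy_uniform_is_one(self):
        agg = make_agg(np.full(32, 3.3))
        assert spectral_entropy(agg, full_band(agg)) == pytest.approx(1.0)

    def test_entropy_delta_is_zero(self):
        power = np.zeros(32)
        power[10] = 7.0
        agg = make_agg(power)
        assert spectral_entropy(agg, full_band(agg)) == pytest.approx(0.0)

    def test_entropy_two_equal_bins_of_four(self):
        agg = make_agg([0.5, 0.5, 0.0, 0.0])
        assert spectral_entropy(agg, full_band(agg)) == pytest.approx(
            np.log(2) / np.log(4)
        )

    def test_spread_delta_is_zero_and_centroid_at_delta(self):
        power = np.zeros(41)
        power[12] = 2.0
        agg = make_agg(power, 0.0, 4.0)
        band = full_band(agg)
        assert spectral_spread(agg, band) == pytest.approx(0.0)
        assert spectral_centroid(agg, band) == pytest.approx(agg.mod_freqs_hz[12])

    def test_spread_two_point_symmetric(self):
        # equal mass at 1.0 and 2.0 Hz -> centroid 1.5 Hz, spread 0.5 Hz
        freqs = np.linspace(0, 4, 41)
        power = np.zeros(41)
        power[np.argmin(np.abs(freqs - 1.0))] = 1.0
        power[np.argmin(np.abs(freqs - 2.0))] = 1.0
        agg = AggregatedModSpectrum(power, freqs, (2, 8))
        band = full_band(agg)
        assert spectral_centroid(agg, band) == pytest.approx(1.5)
        assert spectral_spread(agg, band) == pytest.approx(0.5)

    def test_spread_uniform_matches_discrete_uniform_std(self):
        n = 57
        agg = make_agg(np.ones(n), 0.8, 3.6)
        df = agg.mod_freqs_hz[1] - agg.mod_freqs_hz[0]
        expected = df * np.sqrt((n**2 - 1) / 12.0)  # discrete-uniform std
        assert spectral_spread(agg, full_band(agg)) == pytest.approx(expected)

    def test_spread_literal_variance_option(self):
        agg = make_agg([1.0, 0, 0, 0, 1.0], 1.0, 2.0)
        assert spectral_spread(agg, full_band(agg), sqrt=False) == pytest.approx(0.25)

    def test_crest_flat_is_one(self):
        agg = make_agg(np.full(16, 2.0))
        assert spectral_crest(agg, full_band(agg)) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [4, 16, 93])
    def test_crest_delta_equals_bin_count(self, n):
        power = np.zeros(n)
        power[n // 2] = 1.0
        agg = make_agg(power)
        assert spectral_crest(agg, full_band(agg)) == pytest.approx(n)

    def test_crest_hand_computed(self):
        agg = make_agg([3.0, 1.0, 1.0, 1.0])
        assert spectral_crest(agg, full_band(agg)) == pytest.approx(2.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    seed=st.integers(min_value=0, max_value=2**16),
    scale=st.floats(min_value=1e-3, max_value=1e3),
    n=st.integers(min_value=4, max_value=120),
)
def test_descriptor_bounds_and_scale_invariance(seed, scale, n):
    rng = np.random.default_rng(seed)
    power = rng.random(n) + 1e-9
    agg, scaled = make_agg(power), make_agg(scale * power)
    band = full_band(agg)
    ent = spectral_entropy(agg, band)
    sprd = spectral_spread(agg, band)
    crst = spectral_crest(agg, band)
    assert 0.0 <= ent <= 1.0
    assert 1.0 <= crst <= band.n_bins + 1e-9
    half_range = (agg.mod_freqs_hz[-1] - agg.mod_freqs_hz[0]) / 2
    assert 0.0 <= sprd <= half_range + 1e-9
    assert spectral_entropy(scaled, band) == pytest.approx(ent)
    assert spectral_spread(scaled, band) == pytest.approx(sprd)
    assert spectral_crest(scaled, band) == pytest.approx(crst)


class TestFullChain:
    def test_fmain_matches_realized_heart_rate(self):
        record = p.synthesize_record("s", "green", 32, hr_profile=1.5, seed=4)
        filtered = p.attenuate_breathing(record)
        epoch = p.epoch_record(filtered)[2]
        from ppgsqi.modspec import epoch_modulation_spectrum

        agg = epoch_modulation_spectrum(epoch.samples, epoch.fs)
        sq = p.compute_proposed_sqis(epoch.samples, epoch.fs)
        beats = record.beat_times_s
        beats = beats[(beats >= epoch.start_s) & (beats < epoch.start_s + 8)]
        realized = 1.0 / np.mean(np.diff(beats))
        assert abs(sq.fmain_hz - realized) <= agg.resolution_hz

    def test_all_zero_epoch_is_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            p.compute_proposed_sqis(np.zeros(2000), 250.0)

    def test_scale_invariance_on_real_epoch(self, clean_epoch):
        a = p.compute_proposed_sqis(clean_epoch.samples, clean_epoch.fs)
        b = p.compute_proposed_sqis(17.0 * clean_epoch.samples, clean_epoch.fs)
        assert a.entms == pytest.approx(b.entms)
        assert a.sprdms == pytest.approx(b.sprdms)
        assert a.crstms == pytest.approx(b.crstms)
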