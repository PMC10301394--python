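"""Modulation-spectrum shape signal-quality indexes: entMS, sprdMS, crstMS.

Pipeline per 8 s epoch: compute the aggregated modulation spectrum, locate
the fundamental lobe (fmain, the modulation frequency of the spectrum
maximum inside the plausible heart-rate band 0.8-3.6 Hz), decide whether a
first harmonic lobe exists near 2*fmain, restrict the spectrum to either the
main-lobe band (0.8, 1.5*fmain) Hz or the full (0.8, 3.6) Hz band, and
compute three shape descriptors of the band-limited spectrum:

- spectral entropy (entMS): uniformity, normalized to [0, 1] by the bin
  count. A clean PPG concentrates energy in one lobe -> low entropy.
- spectral spread (sprdMS): standard deviation, in Hz, of the spectrum about
  its centroid. Lower for clean signals.
- spectral crest (crstMS): max-to-mean ratio, in [1, n_bins]. Higher for
  clean signals.

All three are invariant to amplitude scaling of the input signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .modspec import (
    DEFAULT_AGG_BAND_HZ,
    DEFAULT_OVERLAP_FRAC,
    DEFAULT_WIN_DUR_S,
    AggregatedModSpectrum,
    epoch_modulation_spectrum,
)

__all__ = [
    "LobeBand",
    "ProposedSqis",
    "DegenerateSpectrumError",
    "find_fundamental",
    "detect_harmonic",
    "select_band",
    "spectral_entropy",
    "spectral_centroid",
    "spectral_spread",
    "spectral_crest",
    "compute_proposed_sqis",
]

#: Modulation-frequency search band, Hz (plausible heart rates, 48-216 bpm).
SEARCH_BAND_HZ = (0.8, 3.6)


class DegenerateSpectrumError(ValueError):
    """Raised when the spectrum carries no power in the analysis band."""


@dataclass(frozen=True)
class LobeBand:
    """Fundamental-lobe localization result and descriptor band."""

    fmain_hz: float
    harmonic_found: bool
    band_hz: tuple[float, float]
    bin_range: tuple[int, int]  # inclusive indices into the aggregated spectrum

    @property
    def n_bins(self) -> int:
        return self.bin_range[1] - self.bin_range[0] + 1


@dataclass(frozen=True)
class ProposedSqis:
    entms: float
    sprdms: float
    crstms: float
    fmain_hz: float
    harmonic_found: bool
    band_hz: tuple[float, float]


def _band_mask(agg: AggregatedModSpectrum, band: tuple[float, float]) -> np.ndarray:
    return (agg.mod_freqs_hz >= band[0]) & (agg.mod_freqs_hz <= band[1])


def find_fundamental(
    agg: AggregatedModSpectrum,
    search_band: tuple[float, float] = SEARCH_BAND_HZ,
) -> float:
    """Modulation frequency of the aggregated-spectrum maximum in the band.

    Ties break toward the lower frequency. For a clean PPG this equals the
    heart rate; for noisy signals it can be arbitrary.
    """
    mask = _band_mask(agg, search_band)
    if not mask.any():
        raise ValueError(f"search band {search_band} outside modulation axis")
    power = agg.power[mask]
    if not np.any(power > 0):
        raise DegenerateSpectrumError("no power in the fundamental search band")
    return float(agg.mod_freqs_hz[mask][int(np.argmax(power))])


def detect_harmonic(
    agg: AggregatedModSpectrum,
    fmain_hz: float,
    rel_height: float = 0.05,
    tol_bins: int = 2,
    search_max_hz: float = SEARCH_BAND_HZ[1],
    rule: str = "detected",
) -> bool:
    """Is there a first-harmonic lobe near 2*fmain?

    With the default rule a harmonic exists iff ``2*fmain`` still lies
    inside the modulation search range and a local maximum of the aggregated
    power occurs within ``tol_bins`` of ``2*fmain`` with height at least
    ``rel_height`` times the power at ``fmain``. ``rule="literal"`` instead
    requires ``fmain > search_max_hz / 2`` (under which the harmonic lies
    outside the search range and is looked up on the full modulation axis).
    """
    power = agg.power
    freqs = agg.mod_freqs_hz
    if rule == "literal":
        if not fmain_hz > search_max_hz / 2:
            return False
    elif rule == "detected":
        if 2.0 * fmain_hz > search_max_hz:
            return False
    else:
        raise ValueError(f"unknown harmonic rule {rule!r}")

    target = 2.0 * fmain_hz
    if target > freqs[-1]:
        return False
    center = int(np.argmin(np.abs(freqs - target)))
    p_main = power[int(np.argmin(np.abs(freqs - fmain_hz)))]
    lo = max(1, center - tol_bins)
    hi = min(len(power) - 2, center + tol_bins)
    for k in range(lo, hi + 1):
        is_local_max = power[k] >= power[k - 1] and power[k] >= power[k + 1]
        if is_local_max and power[k] >= rel_height * p_main:
            return True
    return False


def select_band(
    fmain_hz: float,
    harmonic_found: bool,
    mod_freqs_hz: np.ndarray,
    search_band: tuple[float, float] = SEARCH_BAND_HZ,
) -> LobeBand:
    """Descriptor band: (0.8, 1.5*fmain) Hz when a harmonic was found — so
    only the main lobe is kept — else the full (0.8, 3.6) Hz range.

    Bin range is inclusive on both edges. Raises if the band resolves to
    fewer than 4 modulation bins.
    """
    b_lo = search_band[0]
    b_hi = 1.5 * fmain_hz if harmonic_found else search_band[1]
    eps = 1e-9  # keep exact band edges inclusive despite float rounding
    idx = np.flatnonzero((mod_freqs_hz >= b_lo - eps) & (mod_freqs_hz <= b_hi + eps))
    if len(idx) < 4:
        raise ValueError(
            f"band ({b_lo:.2f}, {b_hi:.2f}) Hz contains {len(idx)} modulation "
            "bins (< 4); increase the modulation-axis resolution"
        )
    return LobeBand(
        fmain_hz=fmain_hz,
        harmonic_found=harmonic_found,
        band_hz=(b_lo, b_hi),
        bin_range=(int(idx[0]), int(idx[-1])),
    )


def _band_pk(agg: AggregatedModSpectrum, band: LobeBand) -> np.ndarray:
    b1, b2 = band.bin_range
    pk = agg.power[b1 : b2 + 1]
    total = pk.sum()
    if total <= 0:
        raise DegenerateSpectrumError("zero total power in descriptor band")
    return pk / total


def spectral_entropy(agg: AggregatedModSpectrum, band: LobeBand) -> float:
    """Normalized Shannon entropy of the band spectrum, in [0, 1].

    ``-sum(pk log pk) / log(n_bins)`` with the band power normalized to sum
    to one; zero bins contribute nothing. 1 for a uniform spectrum, 0 for a
    single-bin spectrum.
    """
    if band.n_bins < 2:
        raise ValueError("entropy undefined for fewer than 2 bins")
    pk = _band_pk(agg, band)
    nz = pk[pk > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(band.n_bins))


def spectral_centroid(agg: AggregatedModSpectrum, band: LobeBand) -> float:
    """Power-weighted mean modulation frequency of the band, Hz."""
    pk = _band_pk(agg, band)
    fk = agg.mod_freqs_hz[band.bin_range[0] : band.bin_range[1] + 1]
    return float((fk * pk).sum())


def spectral_spread(
    agg: AggregatedModSpectrum, band: LobeBand, sqrt: bool = True
) -> float:
    """Standard deviation (Hz) of the band spectrum about its centroid.

    With ``sqrt=False`` the power-weighted variance (Hz^2) is returned
    instead of its square root.
    """
    pk = _band_pk(agg, band)
    fk = agg.mod_freqs_hz[band.bin_range[0] : band.bin_range[1] + 1]
    centroid = (fk * pk).sum()
    var = ((fk - centroid) ** 2 * pk).sum()
    return float(np.sqrt(var)) if sqrt else float(var)


def spectral_crest(agg: AggregatedModSpectrum, band: LobeBand) -> float:
    """Max-to-mean ratio of the band spectrum: 1 (flat) to n_bins (delta)."""
    pk = _band_pk(agg, band)
    return float(pk.max() / pk.mean())


def compute_proposed_sqis(
    samples: np.ndarray,
    fs: float,
    *,
    win_dur_s: float = DEFAULT_WIN_DUR_S,
    overlap_frac: float = DEFAULT_OVERLAP_FRAC,
    agg_band_hz: tuple[float, float] = DEFAULT_AGG_BAND_HZ,
    search_band: tuple[float, float] = SEARCH_BAND_HZ,
    rel_height: float = 0.05,
    tol_bins: int = 2,
    harmonic_rule: str = "detected",
    sqrt_spread: bool = True,
) -> ProposedSqis:
    """Full descriptor chain for one epoch.

    Chains STFT -> modulation spectrogram -> 2-8 Hz aggregation ->
    fundamental localization -> harmonic detection -> band selection ->
    entMS / sprdMS / crstMS. Deterministic; raises
    :class:`DegenerateSpectrumError` on all-zero input.
    """
    agg = epoch_modulation_spectrum(
        samples,
        fs,
        win_dur_s=win_dur_s,
        overlap_frac=overlap_frac,
        agg_band_hz=agg_band_hz,
    )
    fmain = find_fundamental(agg, search_band)
    harmonic = detect_harmonic(
        agg, fmain, rel_height, tol_bins, search_band[1], harmonic_rule
    )
    band = select_band(fmain, harmonic, agg.mod_freqs_hz, search_band)
    return ProposedSqis(
        entms=spectral_entropy(agg, band),
        sprdms=spectral_spread(agg, band, sqrt=sqrt_spread),
        crstms=spectral_crest(agg, band),
        fmain_hz=fmain,
        harmonic_found=harmonic,
        band_hz=band.band_hz,
    )
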