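"""Benchmark signal-quality indexes: statistical, frequency and template based.

Three families commonly used for PPG quality assessment:

- ``benchstat``: zero-crossing count, skewness, kurtosis, the ratio
  var(|x|)/var(x), and the first two autocorrelation peak heights.
- ``benchfreq``: Welch-PSD band-power ratios around the cardiac band
  (1-2.25 Hz) and the pulse-energy band (1-8 Hz), with and without the
  sub-1 Hz (DC/residual-baseline) region.
- ``benchtemplate``: per-beat metrics computed on templates segmented
  around systolic peaks found by a multiple-moving-average (MMA) consensus
  detector, plus a zero-gradient-per-peak count (cardioSQI).

``compute_all_sqis`` assembles the 16 benchmark values together with the
three modulation-spectrum descriptors into one named vector per epoch;
metrics that cannot be computed (flat-line epochs, fewer than two detected
beats) are flagged as NaN, never silently imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .proposed import DegenerateSpectrumError, compute_proposed_sqis
from .records import Epoch

__all__ = [
    "PsdEstimate",
    "BeatSegmentation",
    "stat_sqis",
    "welch_psd",
    "band_power",
    "freq_sqis",
    "mma_detect_peaks",
    "extract_templates",
    "template_sqis",
    "cardio_sqi",
    "compute_all_sqis",
    "feature_table",
    "SQI_NAMES",
    "FEATURE_FAMILIES",
]

#: Canonical feature order of the 19-entry SQI vector.
SQI_NAMES = [
    "zcSQI",
    "sSQI",
    "kSQI",
    "elgSQI",
    "ACPeak1",
    "ACPeak2",
    "RelP",
    "iorSQI",
    "fSNR",
    "iorSQI_no_DC",
    "fSNR_no_DC",
    "MedRelP",
    "beatElg",
    "beatSSQI",
    "beatKSQI",
    "cardioSQI",
    "entMS",
    "sprdMS",
    "crstMS",
]

FEATURE_FAMILIES = {
    "benchstat": ["zcSQI", "sSQI", "kSQI", "elgSQI", "ACPeak1", "ACPeak2"],
    "benchfreq": ["RelP", "iorSQI", "fSNR", "iorSQI_no_DC", "fSNR_no_DC"],
    "benchtemplate": ["MedRelP", "beatElg", "beatSSQI", "beatKSQI", "cardioSQI"],
    "proposed": ["entMS", "sprdMS", "crstMS"],
}
FEATURE_FAMILIES["benchmark"] = (
    FEATURE_FAMILIES["benchstat"]
    + FEATURE_FAMILIES["benchfreq"]
    + FEATURE_FAMILIES["benchtemplate"]
)
FEATURE_FAMILIES["all"] = SQI_NAMES

#: Kurtosis convention: Pearson (a normal distribution scores 3).
KURTOSIS_FISHER = False

DEFAULT_MMA_WINDOWS_S = (0.5, 1.0, 1.5, 2.0)
MMA_MATCH_TOL_S = 0.1
AC_REFRACTORY_S = 0.25


@dataclass
class PsdEstimate:
    """Welch power-spectral-density estimate over [0, fs/2]."""

    freqs_hz: np.ndarray
    power: np.ndarray
    fs: float
    seg_len_s: float
    overlap_frac: float
    window: str


@dataclass
class BeatSegmentation:
    """Systolic peak indices and the beat templates cut around them."""

    peak_indices: np.ndarray
    templates: list[np.ndarray]
    template_half_width_s: float


# ---------------------------------------------------------------------------
# benchstat


def stat_sqis(samples: np.ndarray, fs: float) -> dict[str, float]:
    """Statistical SQIs of one epoch.

    The epoch is mean-centered first (raw PPG carries a DC offset that would
    make literal zero-crossings meaningless). Returns zcSQI (sign-change
    count), sSQI / kSQI (sample skewness, Pearson kurtosis), elgSQI
    (var(|x|)/var(x)) and ACPeak1/2 (heights of the first two local maxima
    of the normalized autocorrelation beyond a 0.25 s refractory lag). A
    constant epoch yields NaN for the variance-based entries.
    """
    x = np.asarray(samples, dtype=float)
    xc = x - x.mean()
    out: dict[str, float] = {}

    out["zcSQI"] = float(np.count_nonzero(np.diff(np.signbit(xc))))
    var = xc.var()
    if var <= 0:
        out.update(sSQI=np.nan, kSQI=np.nan, elgSQI=np.nan,
                   ACPeak1=np.nan, ACPeak2=np.nan)
        return out
    out["sSQI"] = float(stats.skew(xc))
    out["kSQI"] = float(stats.kurtosis(xc, fisher=KURTOSIS_FISHER))
    out["elgSQI"] = float(np.var(np.abs(xc)) / var)

    acf = sps.correlate(xc, xc, mode="full")[len(xc) - 1 :]
    acf = acf / acf[0]  # biased normalized autocorrelation
    refractory = int(round(AC_REFRACTORY_S * fs))
    peaks, _ = sps.find_peaks(acf)
    peaks = peaks[peaks >= refractory]
    out["ACPeak1"] = float(acf[peaks[0]]) if len(peaks) >= 1 else np.nan
    out["ACPeak2"] = float(acf[peaks[1]]) if len(peaks) >= 2 else np.nan
    return out


# ---------------------------------------------------------------------------
# benchfreq


def welch_psd(
    samples: np.ndarray,
    fs: float,
    seg_len_s: float = 2.0,
    overlap_frac: float = 0.5,
    window: str = "hamming",
) -> PsdEstimate:
    """Welch PSD; segments shorter than the signal fall back to one segment."""
    x = np.asarray(samples, dtype=float)
    nperseg = min(len(x), int(round(seg_len_s * fs)))
    freqs, power = sps.welch(
        x,
        fs=fs,
        window=window,
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap_frac)),
        detrend="constant",
    )
    return PsdEstimate(freqs, power, fs, seg_len_s, overlap_frac, window)


def band_power(psd: PsdEstimate, f_lo: float, f_hi: float) -> float:
    """Sum of PSD bins with f_lo <= f < f_hi (Nyquist edge inclusive)."""
    mask = (psd.freqs_hz >= f_lo) & (psd.freqs_hz < f_hi)
    if f_hi >= psd.freqs_hz[-1]:
        mask |= psd.freqs_hz == psd.freqs_hz[-1]
    return float(psd.power[mask].sum())


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else np.nan


def freq_sqis(psd: PsdEstimate) -> dict[str, float]:
    """Band-power-ratio SQIs from one epoch-level PSD.

    RelP = P(1-2.25)/P(1-8); iorSQI = P(1-8)/(P(0-1)+P(8-fs/2));
    fSNR = P(1-2.25)/P(0-fs/2); the no-DC variants replace the denominators
    with P(1-fs/2). The asymmetric denominators are intentional and follow
    the metric definitions as used in the PPG quality literature.
    """
    nyq = psd.fs / 2.0
    p_card = band_power(psd, 1.0, 2.25)
    p_pulse = band_power(psd, 1.0, 8.0)
    p_out = band_power(psd, 0.0, 1.0) + band_power(psd, 8.0, nyq)
    p_all = band_power(psd, 0.0, nyq)
    p_no_dc = band_power(psd, 1.0, nyq)
    return {
        "RelP": _ratio(p_card, p_pulse),
        "iorSQI": _ratio(p_pulse, p_out),
        "fSNR": _ratio(p_card, p_all),
        "iorSQI_no_DC": _ratio(p_pulse, p_no_dc),
        "fSNR_no_DC": _ratio(p_card, p_no_dc),
    }


# ---------------------------------------------------------------------------
# benchtemplate


def _candidates_above_ma(x: np.ndarray, win: int) -> np.ndarray:
    """One candidate peak (signal argmax) per region where x exceeds its
    centered moving average (edge reflection)."""
    from scipy.ndimage import uniform_filter1d

    ma = uniform_filter1d(x, size=win, mode="reflect")
    above = x > ma
    if not above.any():
        return np.empty(0, dtype=int)
    a = above.astype(np.int8)
    run_starts = np.flatnonzero(np.diff(np.concatenate(([0], a))) == 1)
    run_ends = np.flatnonzero(np.diff(np.concatenate((a, [0]))) == -1)
    return np.array(
        [s + int(np.argmax(x[s : e + 1])) for s, e in zip(run_starts, run_ends)],
        dtype=int,
    )


def mma_detect_peaks(
    samples: np.ndarray,
    fs: float,
    window_sizes_s: Sequence[float] = DEFAULT_MMA_WINDOWS_S,
    match_tol_s: float = MMA_MATCH_TOL_S,
) -> np.ndarray:
    """Multiple-moving-average consensus peak detector.

    For each moving-average window size, candidate peaks are the signal
    maxima inside regions where the signal exceeds its centered moving
    average. A final peak requires a matching candidate (within
    ``match_tol_s``) in every window's candidate set; its position is the
    median of the matched candidates. The consensus across window scales
    suppresses spurious maxima (e.g., diastolic peaks) that only emerge at
    the shortest scales. Returns an empty array if no consensus exists.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 2 * fs:
        raise ValueError("epoch must be at least 2 s long for the MMA detector")
    tol = int(round(match_tol_s * fs))
    cand_sets = [
        _candidates_above_ma(x, max(2, int(round(w * fs)))) for w in window_sizes_s
    ]
    if any(len(c) == 0 for c in cand_sets):
        return np.empty(0, dtype=int)

    anchors = cand_sets[0]
    final: list[int] = []
    for p in anchors:
        matched = [p]
        ok = True
        for other in cand_sets[1:]:
            j = int(np.argmin(np.abs(other - p)))
            if abs(int(other[j]) - int(p)) <= tol:
                matched.append(int(other[j]))
            else:
                ok = False
                break
        if ok:
            final.append(int(round(float(np.median(matched)))))
    if not final:
        return np.empty(0, dtype=int)
    # merge consensus peaks closer than the tolerance
    final_arr = np.array(sorted(set(final)), dtype=int)
    keep = [final_arr[0]]
    for p in final_arr[1:]:
        if p - keep[-1] <= tol:
            keep[-1] = int(round((keep[-1] + p) / 2))
        else:
            keep.append(int(p))
    return np.array(keep, dtype=int)


def extract_templates(
    samples: np.ndarray, fs: float, peak_indices: np.ndarray
) -> BeatSegmentation:
    """Cut one template per beat, adapted to the median peak-to-peak interval.

    Template half-width is half the median inter-peak interval; beats whose
    template would be truncated by the epoch edges are dropped.
    """
    peaks = np.asarray(peak_indices, dtype=int)
    if len(peaks) < 2:
        raise ValueError("need >= 2 detected peaks to segment beat templates")
    half = int(round(0.5 * float(np.median(np.diff(peaks)))))
    half = max(half, 1)
    x = np.asarray(samples, dtype=float)
    templates = [
        x[p - half : p + half] for p in peaks if p - half >= 0 and p + half <= len(x)
    ]
    return BeatSegmentation(peaks, templates, half / fs)


def _distribution_moments(template: np.ndarray, fs: float) -> tuple[float, float]:
    """Skewness and Pearson kurtosis of a beat treated as a probability
    distribution over time (template shifted nonnegative, mass normalized)."""
    t = np.asarray(template, dtype=float)
    p = t - t.min()
    mass = p.sum()
    if mass <= 0:
        return np.nan, np.nan
    p = p / mass
    tau = np.arange(len(p)) / fs
    mu = (tau * p).sum()
    var = ((tau - mu) ** 2 * p).sum()
    if var <= 0:
        return np.nan, np.nan
    sd = np.sqrt(var)
    skew = (((tau - mu) / sd) ** 3 * p).sum()
    kurt = (((tau - mu) / sd) ** 4 * p).sum()
    return float(skew), float(kurt)


def template_sqis(seg: BeatSegmentation, fs: float) -> dict[str, float]:
    """Per-beat SQIs reduced across templates.

    Median reductions for MedRelP (per-beat PSD ratio P(1-2.25)/P(0-8)) and
    beatElg; mean reductions for the distribution skewness and kurtosis.
    Degenerate (zero-mass) templates are excluded.
    """
    if len(seg.templates) < 2:
        raise ValueError("need >= 2 full templates for template SQIs")
    relps, elgs, skews, kurts = [], [], [], []
    for t in seg.templates:
        psd = welch_psd(t, fs)
        relps.append(_ratio(band_power(psd, 1.0, 2.25), band_power(psd, 0.0, 8.0)))
        var = t.var()
        elgs.append(np.var(np.abs(t - t.mean())) / var if var > 0 else np.nan)
        sk, ku = _distribution_moments(t, fs)
        skews.append(sk)
        kurts.append(ku)
    return {
        "MedRelP": float(np.nanmedian(relps)),
        "beatElg": float(np.nanmedian(elgs)),
        "beatSSQI": float(np.nanmean(skews)),
        "beatKSQI": float(np.nanmean(kurts)),
    }


def cardio_sqi(samples: np.ndarray, peak_indices: np.ndarray) -> float:
    """Zero-gradient count per detected peak; lower is cleaner.

    Counts sign changes of the first difference (local maxima + minima). As
    noise increases, zero-gradients multiply faster than detected peaks.
    """
    d = np.diff(np.asarray(samples, dtype=float))
    s = np.sign(d)
    s = s[s != 0]
    zero_grad = int(np.count_nonzero(np.diff(s) != 0))
    return float(zero_grad / max(1, len(peak_indices)))


# ---------------------------------------------------------------------------
# assembly


def compute_all_sqis(epoch: Epoch, **proposed_kwargs) -> dict[str, float]:
    """The full 19-entry named SQI vector for one epoch.

    Statistical and frequency SQIs always produce a value (NaN on degenerate
    input); template SQIs are NaN when fewer than two beats are detected;
    the modulation descriptors are NaN when the epoch spectrum is degenerate
    (e.g., an all-zero epoch raises upstream and is flagged here).
    """
    x = epoch.samples
    fs = epoch.fs
    out: dict[str, float] = {name: np.nan for name in SQI_NAMES}

    out.update(stat_sqis(x, fs))
    out.update(freq_sqis(welch_psd(x, fs)))

    peaks = mma_detect_peaks(x, fs)
    out["cardioSQI"] = cardio_sqi(x, peaks)
    if len(peaks) >= 2:
        seg = extract_templates(x, fs, peaks)
        if len(seg.templates) >= 2:
            out.update(template_sqis(seg, fs))

    try:
        p = compute_proposed_sqis(x, fs, **proposed_kwargs)
    except DegenerateSpectrumError:
        pass
    else:
        out["entMS"] = p.entms
        out["sprdMS"] = p.sprdms
        out["crstMS"] = p.crstms
    return out


def feature_table(epochs: Iterable[Epoch], **proposed_kwargs) -> pd.DataFrame:
    """One row per epoch: metadata, label and the 19 SQI columns."""
    rows = []
    for epoch in epochs:
        row = {
            "subject_id": epoch.subject_id,
            "wavelength": epoch.wavelength,
            "start_s": epoch.start_s,
            "label": epoch.label,
        }
        row.update(compute_all_sqis(epoch, **proposed_kwargs))
        rows.append(row)
    return pd.DataFrame(rows)
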