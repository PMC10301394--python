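"""Synthetic multi-wavelength PPG cohort generator.

Generates quasi-periodic PPG records — systolic peak, dicrotic notch and
diastolic peak per cardiac cycle, with cycle-to-cycle heart-rate jitter —
contaminated by periodic motion artifacts (walking / squatting cadence with
slow frequency drift and amplitude modulation) and broadband noise segments.
Every record carries ground-truth quality annotations so the full clean vs.
noisy analysis chain can be exercised without access to recorded data.

Beat morphology is built as a sum of wrapped Gaussian bumps on the cycle
phase grid: a large systolic bump, a smaller diastolic bump riding on the
systolic shoulder, and a narrow negative bump carving the dicrotic notch.
This guarantees the three annotation landmarks by construction while staying
smooth and fully parameterizable.

All outputs are pure functions of their arguments and a seed: per-subject and
per-record random streams are derived from one master ``SeedSequence`` so
cohorts are bit-reproducible and subjects mutually independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .records import (
    WAVELENGTHS,
    AnnotationSpan,
    PpgRecord,
    sample_labels_to_spans,
    spans_to_sample_labels,
)

__all__ = [
    "BeatTemplate",
    "NoiseSpec",
    "MorphologyError",
    "InvalidSpanError",
    "make_beat_template",
    "synthesize_record",
    "make_cohort",
    "WAVELENGTH_NOISE_SCALE",
]

#: Plausible heart-rate band, Hz (48-216 bpm).
HR_BAND_HZ = (0.8, 3.6)

#: Relative noise sensitivity per wavelength: green PPG is more robust to
#: motion artifacts than red and infrared.
WAVELENGTH_NOISE_SCALE = {"green": 0.6, "red": 1.0, "infrared": 1.1}

#: Multiplicative cycle-length jitter (standard deviation, fraction of cycle).
DEFAULT_JITTER_FRAC = 0.02


class MorphologyError(ValueError):
    """Raised when beat-template parameters violate landmark ordering."""


class InvalidSpanError(ValueError):
    """Raised when a noise span does not fit inside the record."""


@dataclass(frozen=True)
class BeatTemplate:
    """One cardiac cycle of PPG waveform with its morphology parameters.

    Amplitudes are dimensionless and relative to the systolic bump; the
    fractional positions locate the systolic peak, dicrotic notch and
    diastolic peak within the cycle, in that order.
    """

    duration_s: float
    samples: np.ndarray
    systolic_amp: float
    diastolic_amp: float
    notch_depth: float
    systolic_frac: float
    notch_frac: float
    diastolic_frac: float


@dataclass(frozen=True)
class NoiseSpec:
    """Specification of one contaminated interval within a record.

    ``motion_amp`` is the ratio of the motion fundamental's peak-to-peak
    amplitude to the clean signal's peak-to-peak amplitude inside the span;
    amplitudes >= 1 destroy the beat morphology (noisy), 0.3-1 distort it
    while leaving the periodicity visible (okay), and < 0.3 are treated as
    negligible (clean). ``broadband_snr_db`` follows the same idea: spans at
    <= 5 dB SNR are noisy, anything milder is okay.
    """

    kind: str = "periodic_motion"
    motion_freq_hz: float = 2.0
    motion_amp: float = 0.0
    broadband_snr_db: float = 0.0
    onset_s: float = 0.0
    offset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "periodic_motion", "broadband", "mixed"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.motion_amp < 0:
            raise ValueError("motion_amp must be >= 0")
        if self.offset_s <= self.onset_s and self.kind != "none":
            raise InvalidSpanError(
                f"noise span must have onset_s < offset_s, got "
                f"[{self.onset_s}, {self.offset_s}]"
            )

    @property
    def label(self) -> str:
        """Ground-truth quality label implied by this spec."""
        if self.kind == "none":
            return "clean"
        labels = []
        if self.kind in ("periodic_motion", "mixed"):
            if self.motion_amp >= 1.0:
                labels.append("noisy")
            elif self.motion_amp >= 0.3:
                labels.append("okay")
            else:
                labels.append("clean")
        if self.kind in ("broadband", "mixed"):
            labels.append("noisy" if self.broadband_snr_db <= 5.0 else "okay")
        severity = {"clean": 0, "okay": 1, "noisy": 2}
        return max(labels, key=severity.__getitem__)


def _wrapped_gaussian(phase: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Gaussian bump on the unit circle (periodic in phase)."""
    d = (phase - mu + 0.5) % 1.0 - 0.5
    return np.exp(-0.5 * (d / sigma) ** 2)


def _beat_waveform(
    n: int,
    systolic_amp: float,
    diastolic_amp: float,
    notch_depth: float,
    systolic_frac: float,
    notch_frac: float,
    diastolic_frac: float,
    systolic_width: float,
    notch_width: float,
    diastolic_width: float,
) -> np.ndarray:
    phase = np.arange(n) / n
    w = systolic_amp * _wrapped_gaussian(phase, systolic_frac, systolic_width)
    w += diastolic_amp * _wrapped_gaussian(phase, diastolic_frac, diastolic_width)
    if notch_depth != 0.0:
        w -= notch_depth * _wrapped_gaussian(phase, notch_frac, notch_width)
    return w


def make_beat_template(
    heart_rate_hz: float,
    fs: float = 250.0,
    *,
    systolic_amp: float = 1.0,
    diastolic_amp: float = 0.35,
    notch_depth: float = 0.12,
    systolic_frac: float = 0.50,
    notch_frac: float = 0.64,
    diastolic_frac: float = 0.72,
    systolic_width: float = 0.10,
    notch_width: float = 0.03,
    diastolic_width: float = 0.06,
) -> BeatTemplate:
    """Build one cardiac cycle sampled at ``fs``.

    The default morphology yields exactly one global maximum (systolic),
    one local minimum after it (dicrotic notch) and one secondary local
    maximum (diastolic peak), with the waveform value at the notch lying
    strictly between ``diastolic_amp`` and ``systolic_amp``; with
    ``notch_depth=0`` the diastolic bump merges into the systolic shoulder
    and only the systolic maximum remains. Wrapped bumps make the waveform
    exactly periodic, and the default landmark positions start the cycle at
    the inter-beat trough, so concatenated cycles are continuous (first and
    last samples agree to well under 1% of the systolic amplitude).

    Raises
    ------
    ValueError
        If ``heart_rate_hz`` lies outside the 0.8-3.6 Hz plausible band.
    MorphologyError
        If the fractional landmark positions are not strictly ordered or the
        amplitude ordering ``systolic_amp > diastolic_amp > 0`` is violated.
    """
    lo, hi = HR_BAND_HZ
    if not lo <= heart_rate_hz <= hi:
        raise ValueError(
            f"heart_rate_hz={heart_rate_hz} outside plausible band [{lo}, {hi}] Hz"
        )
    if not systolic_frac < notch_frac < diastolic_frac:
        raise MorphologyError(
            "landmark fractions must satisfy systolic_frac < notch_frac "
            f"< diastolic_frac, got ({systolic_frac}, {notch_frac}, {diastolic_frac})"
        )
    if not systolic_amp > diastolic_amp > 0:
        raise MorphologyError(
            "amplitudes must satisfy systolic_amp > diastolic_amp > 0, got "
            f"({systolic_amp}, {diastolic_amp})"
        )
    duration_s = 1.0 / heart_rate_hz
    n = int(round(fs * duration_s))
    samples = _beat_waveform(
        n,
        systolic_amp,
        diastolic_amp,
        notch_depth,
        systolic_frac,
        notch_frac,
        diastolic_frac,
        systolic_width,
        notch_width,
        diastolic_width,
    )
    return BeatTemplate(
        duration_s=duration_s,
        samples=samples,
        systolic_amp=systolic_amp,
        diastolic_amp=diastolic_amp,
        notch_depth=notch_depth,
        systolic_frac=systolic_frac,
        notch_frac=notch_frac,
        diastolic_frac=diastolic_frac,
    )


def _hr_at(hr_profile, t: float) -> float:
    """Evaluate a piecewise-constant heart-rate profile at time ``t``."""
    if np.isscalar(hr_profile):
        return float(hr_profile)
    hr = None
    for start_s, value in hr_profile:
        if t >= start_s:
            hr = value
    if hr is None:  # before the first breakpoint
        hr = hr_profile[0][1]
    return float(hr)


def _motion_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    freq_hz: float,
    *,
    drift_std: float = 0.05,
    env_depth: float = 0.6,
    n_harmonics: int | None = None,
    harmonic_decay: float | None = None,
) -> np.ndarray:
    """Quasi-periodic motion artifact with unit fundamental amplitude.

    Walking or squatting cadence is not a pure tone: the instantaneous
    frequency follows a slow AR(1) drift (stationary std ``drift_std``) and
    the amplitude is modulated by a smoothed random envelope. Foot strikes
    and posture shifts make the waveform impulsive to a varying degree, so
    the harmonic content is itself randomized per bout: ``n_harmonics``
    defaults to a draw from 2-5 and the per-order amplitude decay from
    0.35-0.75, with random phases. Sparse sharp transients (sensor
    displacement at foot strikes) ride on top of the periodic component.
    """
    if n_harmonics is None:
        n_harmonics = int(rng.integers(2, 6))
    if harmonic_decay is None:
        harmonic_decay = float(rng.uniform(0.35, 0.75))
    block = max(1, int(round(0.25 * fs)))  # 4 Hz update rate for slow processes
    n_blocks = n // block + 2
    rho = 0.97
    innov = rng.standard_normal(n_blocks) * drift_std * math.sqrt(1 - rho**2)
    drift = np.empty(n_blocks)
    drift[0] = rng.standard_normal() * drift_std
    for k in range(1, n_blocks):
        drift[k] = rho * drift[k - 1] + innov[k]
    env_raw = gaussian_filter1d(rng.standard_normal(n_blocks), sigma=4.0)
    env_raw /= max(env_raw.std(), 1e-12)

    t_blocks = np.arange(n_blocks) * block
    t = np.arange(n)
    inst_freq = freq_hz * (1.0 + np.interp(t, t_blocks, drift))
    envelope = np.clip(1.0 + env_depth * np.interp(t, t_blocks, env_raw), 0.15, None)
    phase = 2.0 * np.pi * np.cumsum(inst_freq) / fs
    out = np.sin(phase + rng.uniform(0, 2 * np.pi))
    for h in range(2, 2 + n_harmonics):
        out += harmonic_decay ** (h - 1) * np.sin(h * phase + rng.uniform(0, 2 * np.pi))
    # Arm-swing / stride component at half the step rate: on arm-worn
    # devices, walking noise carries substantial energy at the stride
    # frequency, which overlaps the cardiac band.
    out += rng.uniform(0.4, 1.0) * np.sin(0.5 * phase + rng.uniform(0, 2 * np.pi))
    out = envelope * out
    # Sparse transients: sensor displacement / pressure events produce
    # irregular sharp excursions on top of the periodic component.
    n_events = rng.poisson(0.25 * n / fs)
    for _ in range(n_events):
        c = rng.uniform(0, n)
        width = rng.uniform(0.1, 0.3) * fs
        amp = rng.uniform(1.0, 3.0) * rng.choice([-1.0, 1.0])
        out += amp * np.exp(-0.5 * ((t - c) / (width / 2)) ** 2)
    return out


def _edge_ramp(n: int, fs: float, ramp_s: float = 0.25) -> np.ndarray:
    """Cosine on/off ramp confined to the span, avoiding step transients."""
    ramp = np.ones(n)
    k = min(int(round(ramp_s * fs)), n // 2)
    if k > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
        ramp[:k] = r
        ramp[-k:] = r[::-1]
    return ramp


def synthesize_record(
    subject_id: str,
    wavelength: str,
    duration_s: float,
    fs: float = 250.0,
    hr_profile=1.2,
    noise_specs: Sequence[NoiseSpec] = (),
    seed: int = 0,
    *,
    jitter_frac: float = DEFAULT_JITTER_FRAC,
    sensor_snr_db: float | None = 30.0,
    morphology: dict | None = None,
) -> PpgRecord:
    """Synthesize one PPG record with ground-truth annotations.

    Beats are concatenated following the (piecewise-constant) heart-rate
    profile with multiplicative Gaussian cycle-length jitter, and the beat
    morphology itself fluctuates beat to beat (relative amplitudes and bump
    widths jittered by a few percent, as pulse shape does physiologically);
    each beat is mean-removed so the record has no DC pedestal. Motion and broadband
    noise are added inside their spans; a mild sensor-noise floor
    (``sensor_snr_db``) covers the whole record and does not affect labels.

    ``truth_spans`` mark motion spans as noisy (``motion_amp >= 1``) or okay
    (``0.3 <= motion_amp < 1``) and broadband spans as noisy
    (``snr <= 5 dB``) or okay; all remaining time is clean. Ground-truth
    systolic peak times are returned in ``beat_times_s``.

    Identical arguments and seed give bit-identical output.
    """
    if duration_s < 16:
        raise ValueError("duration_s must be >= 16 s (two overlapping epochs)")
    for spec in noise_specs:
        if spec.kind == "none":
            continue
        if spec.onset_s < 0 or spec.offset_s > duration_s:
            raise InvalidSpanError(
                f"noise span [{spec.onset_s}, {spec.offset_s}] exceeds record "
                f"duration {duration_s}"
            )
    morphology = morphology or {}
    ss = np.random.SeedSequence(seed)
    beat_rng, noise_rng = (np.random.default_rng(c) for c in ss.spawn(2))

    n_total = int(round(duration_s * fs))
    chunks: list[np.ndarray] = []
    beat_peaks: list[float] = []
    n_done = 0
    while n_done < n_total:
        t = n_done / fs
        hr = _hr_at(hr_profile, t)
        cycle_s = (1.0 / hr) * max(0.5, 1.0 + jitter_frac * beat_rng.standard_normal())
        base = dict(morphology)
        beat_morph = {
            "diastolic_amp": base.get("diastolic_amp", 0.35)
            * (1.0 + 0.10 * beat_rng.standard_normal()),
            "notch_depth": base.get("notch_depth", 0.12)
            * (1.0 + 0.15 * beat_rng.standard_normal()),
            "systolic_width": base.get("systolic_width", 0.10)
            * (1.0 + 0.05 * beat_rng.standard_normal()),
            "diastolic_width": base.get("diastolic_width", 0.06)
            * (1.0 + 0.05 * beat_rng.standard_normal()),
        }
        base.update(
            {
                k: float(np.clip(v, *lims))
                for (k, v), lims in zip(
                    beat_morph.items(),
                    ((0.05, 0.9), (0.0, 0.5), (0.05, 0.2), (0.03, 0.15)),
                )
            }
        )
        template = make_beat_template(
            min(max(1.0 / cycle_s, HR_BAND_HZ[0]), HR_BAND_HZ[1]), fs, **base
        )
        beat = template.samples - template.samples.mean()
        peak_idx = n_done + int(np.argmax(beat))
        if peak_idx < n_total:
            beat_peaks.append(peak_idx / fs)
        chunks.append(beat)
        n_done += len(beat)
    samples = np.concatenate(chunks)[:n_total]

    label_arr = spans_to_sample_labels(
        [
            AnnotationSpan(s.onset_s, s.offset_s, s.label)
            for s in noise_specs
            if s.kind != "none" and s.label != "clean"
        ],
        n_total,
        fs,
    )

    for spec in noise_specs:
        if spec.kind == "none":
            continue
        i0 = int(round(spec.onset_s * fs))
        i1 = int(round(spec.offset_s * fs))
        n_span = i1 - i0
        if n_span <= 0:
            continue
        clean_span = samples[i0:i1]
        ramp = _edge_ramp(n_span, fs)
        if spec.kind in ("periodic_motion", "mixed") and spec.motion_amp > 0:
            p2p = float(np.ptp(clean_span))
            amp = 0.5 * spec.motion_amp * p2p  # fundamental p2p = motion_amp * p2p
            noise = _motion_noise(noise_rng, n_span, fs, spec.motion_freq_hz)
            samples[i0:i1] = clean_span + ramp * amp * noise
        if spec.kind in ("broadband", "mixed"):
            var = float(np.var(clean_span))
            std = math.sqrt(var / 10 ** (spec.broadband_snr_db / 10.0))
            samples[i0:i1] = samples[i0:i1] + ramp * std * noise_rng.standard_normal(
                n_span
            )

    if sensor_snr_db is not None:
        # Band-limited noise floor: the analog front end low-passes before
        # digitization, so the floor is smooth at the sample scale.
        from scipy.signal import butter, sosfiltfilt

        floor = noise_rng.standard_normal(n_total)
        sos = butter(4, 15.0, btype="lowpass", fs=fs, output="sos")
        floor = sosfiltfilt(sos, floor)
        floor *= math.sqrt(
            float(np.var(samples)) / 10 ** (sensor_snr_db / 10.0)
        ) / max(floor.std(), 1e-12)
        samples = samples + floor

    nominal_hr = _hr_at(hr_profile, 0.0) if np.isscalar(hr_profile) else None
    return PpgRecord(
        subject_id=subject_id,
        wavelength=wavelength,
        fs=fs,
        samples=samples,
        truth_spans=sample_labels_to_spans(label_arr, fs),
        beat_times_s=np.asarray(beat_peaks),
        nominal_hr_hz=nominal_hr,
    )


def _subject_noise_layout(
    rng: np.random.Generator, duration_s: float
) -> list[NoiseSpec]:
    """Activity layout per subject: squats, incremental treadmill, contact loss.

    Mirrors a protocol of squats and incremental treadmill walking bracketed
    by stationary rest: one strong slow-cadence bout (squats), one walking
    bout whose speed — hence artifact amplitude and step rate — ramps up in
    10 s increments from mild distortion to full corruption, and one
    broadband span (loose sensor contact). The ramp yields a continuum of
    corruption severities, so epochs near the okay/noisy boundary exist for
    every subject. The rest-to-activity proportions put roughly a fifth of
    each record at noisy-level corruption (at unit wavelength scaling),
    with clean epochs the clear majority, as in annotated activity-protocol
    recordings.
    """
    scale = duration_s / 300.0
    # Span boundaries jittered so epochs align differently across subjects.
    j = rng.uniform(-3.0, 3.0, size=3)

    specs = [
        NoiseSpec(
            "periodic_motion",
            motion_freq_hz=rng.uniform(0.45, 0.65),  # squat cadence
            motion_amp=rng.uniform(1.7, 3.0),
            onset_s=(60 + j[0]) * scale,
            offset_s=(90 + j[0]) * scale,
        )
    ]
    cadence = rng.uniform(1.6, 2.6)  # initial step rate, Hz
    base_amp = rng.uniform(0.8, 1.25)
    t0 = (150 + j[1]) * scale
    seg = 10.0 * scale
    for i, ramp in enumerate((0.35, 0.7, 1.2, 2.2)):
        specs.append(
            NoiseSpec(
                "periodic_motion",
                motion_freq_hz=cadence * 1.05**i,  # speed increments
                motion_amp=base_amp * ramp,
                onset_s=t0 + i * seg,
                offset_s=t0 + (i + 1) * seg,
            )
        )
    specs.append(
        NoiseSpec(
            "broadband",
            broadband_snr_db=0.0,
            onset_s=(245 + j[2]) * scale,
            offset_s=(260 + j[2]) * scale,
        )
    )
    return specs


def make_cohort(
    n_subjects: int = 8,
    seed: int = 0,
    *,
    duration_s: float = 300.0,
    fs: float = 250.0,
) -> list[PpgRecord]:
    """Generate a multi-subject, multi-wavelength synthetic cohort.

    Each subject contributes three wavelength records (green, red, infrared)
    sharing the same beat timing; motion-noise amplitude is scaled per
    wavelength (green 0.6, red 1.0, infrared 1.1) so green records are the
    most artifact-robust. Subject resting heart rates are drawn uniformly
    from 0.9-1.8 Hz. Deterministic in ``seed`` via per-subject substreams.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (leave-subjects-out undefined)")
    records: list[PpgRecord] = []
    for subj_idx, child in enumerate(np.random.SeedSequence(seed).spawn(n_subjects)):
        rng = np.random.default_rng(child)
        subject_id = f"S{subj_idx + 1:02d}"
        hr = rng.uniform(0.9, 1.8)
        # inter-subject morphology variability (pulse shape differs by
        # vascular tone, age, measurement site)
        morphology = {
            "diastolic_amp": float(rng.uniform(0.25, 0.45)),
            "notch_depth": float(rng.uniform(0.06, 0.16)),
            "systolic_width": float(rng.uniform(0.085, 0.115)),
            "diastolic_width": float(rng.uniform(0.05, 0.08)),
        }
        layout = _subject_noise_layout(rng, duration_s)
        record_seed = int(rng.integers(2**31))
        for wavelength in WAVELENGTHS:
            scale = WAVELENGTH_NOISE_SCALE[wavelength]
            specs = []
            for spec in layout:
                if spec.kind == "periodic_motion":
                    specs.append(
                        NoiseSpec(
                            spec.kind,
                            motion_freq_hz=spec.motion_freq_hz,
                            motion_amp=spec.motion_amp * scale,
                            onset_s=spec.onset_s,
                            offset_s=spec.offset_s,
                        )
                    )
                else:
                    specs.append(
                        NoiseSpec(
                            spec.kind,
                            broadband_snr_db=spec.broadband_snr_db
                            - 20.0 * math.log10(scale),
                            onset_s=spec.onset_s,
                            offset_s=spec.offset_s,
                        )
                    )
            record = synthesize_record(
                subject_id,
                wavelength,
                duration_s,
                fs,
                hr_profile=hr,
                noise_specs=specs,
                seed=record_seed,
                morphology=morphology,
            )
            records.append(record)
    return records
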