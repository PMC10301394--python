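"""Record preprocessing, fixed-window epoching and majority labeling.

Respiration sits below ~0.5 Hz and would otherwise dominate the low end of
the spectrum, so records are passed through a zero-phase high-pass filter
before analysis. Records are then cut into 8 s windows with 4 s overlap and
each window receives the majority label of the annotations covering it, with
ties broken toward the worse quality.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import signal

from .records import (
    LABEL_SEVERITY,
    LABELS,
    AnnotationSpan,
    Epoch,
    PpgRecord,
)

__all__ = [
    "attenuate_breathing",
    "epoch_record",
    "label_epoch",
    "LabelConflictError",
]

DEFAULT_WINDOW_S = 8.0
DEFAULT_STEP_S = 4.0


class LabelConflictError(ValueError):
    """Raised when overlapping annotation spans carry contradictory labels."""


def attenuate_breathing(
    record: PpgRecord, cutoff_hz: float = 0.5, order: int = 4
) -> PpgRecord:
    """Attenuate sub-cardiac (breathing) frequency content, zero-phase.

    A forward-backward Butterworth high-pass: zero group delay, >= 20 dB
    attenuation one octave below the cutoff, and < 1 dB ripple in the
    heart-rate passband (>= 0.8 Hz) at the default order.

    Raises
    ------
    ValueError
        If ``cutoff_hz`` is not in (0, 0.8): cutoffs at or above 0.8 Hz
        would distort the heart-rate band.
    """
    if not 0 < cutoff_hz < 0.8:
        raise ValueError(
            f"cutoff_hz must be in (0, 0.8) to preserve the HR band, got {cutoff_hz}"
        )
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=record.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, record.samples)
    return record.with_samples(filtered)


def epoch_record(
    record: PpgRecord,
    window_s: float = DEFAULT_WINDOW_S,
    step_s: float = DEFAULT_STEP_S,
    spans: Sequence[AnnotationSpan] | None = None,
) -> list[Epoch]:
    """Cut a record into fixed windows starting at 0, step_s, 2*step_s, ...

    The trailing partial window is discarded, so every epoch has exactly
    ``window_s * fs`` samples. Labels come from ``spans`` (defaulting to the
    record's own truth spans) via :func:`label_epoch`. A record shorter than
    one window yields an empty list with a warning.
    """
    if spans is None:
        spans = record.truth_spans
    n_win = int(round(window_s * record.fs))
    n_step = int(round(step_s * record.fs))
    n = len(record.samples)
    if n < n_win:
        warnings.warn(
            f"record of {n / record.fs:.1f} s is shorter than one {window_s} s "
            "window; no epochs produced",
            stacklevel=2,
        )
        return []
    epochs = []
    for i0 in range(0, n - n_win + 1, n_step):
        start_s = i0 / record.fs
        label, fractions = label_epoch((start_s, start_s + window_s), spans)
        epochs.append(
            Epoch(
                subject_id=record.subject_id,
                wavelength=record.wavelength,
                start_s=record.start_time_s + start_s,
                fs=record.fs,
                samples=record.samples[i0 : i0 + n_win],
                label=label,
                label_fractions=fractions,
            )
        )
    return epochs


def label_epoch(
    epoch_interval: tuple[float, float], spans: Sequence[AnnotationSpan]
) -> tuple[str, tuple[float, float, float]]:
    """Majority-vote label of a window from annotation spans.

    Time not covered by any span defaults to clean. Fractions are the
    covered duration per label divided by the window length (summing to 1);
    the label is their argmax with ties broken toward the worse quality, so
    a borderline window is never called clean.

    Raises
    ------
    LabelConflictError
        If two spans with different labels overlap inside the window.
    """
    start_s, end_s = epoch_interval
    window = end_s - start_s
    if window <= 0:
        raise ValueError("epoch interval must have positive length")

    clipped = []
    for span in spans:
        lo, hi = max(span.start_s, start_s), min(span.end_s, end_s)
        if lo < hi:
            clipped.append((lo, hi, span.label))
    for i, (lo_i, hi_i, lab_i) in enumerate(clipped):
        for lo_j, hi_j, lab_j in clipped[i + 1 :]:
            if lab_i != lab_j and max(lo_i, lo_j) < min(hi_i, hi_j):
                raise LabelConflictError(
                    f"overlapping spans with contradictory labels "
                    f"({lab_i!r} vs {lab_j!r}) in window [{start_s}, {end_s}]"
                )

    covered = {label: 0.0 for label in LABELS}
    for label in LABELS:
        intervals = sorted(
            (lo, hi) for lo, hi, lab in clipped if lab == label
        )
        last_end = -np.inf
        for lo, hi in intervals:  # union length, same-label overlaps merged
            lo = max(lo, last_end)
            if hi > lo:
                covered[label] += hi - lo
                last_end = hi
    marked = covered["okay"] + covered["noisy"]
    covered["clean"] = max(covered["clean"], window - marked)

    fractions = tuple(covered[label] / window for label in LABELS)
    best = max(LABELS, key=lambda lab: (covered[lab] / window, LABEL_SEVERITY[lab]))
    return best, fractions
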