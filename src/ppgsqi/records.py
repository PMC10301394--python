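"""Shared container types for PPG records, annotation spans and epochs.

A :class:`PpgRecord` holds one wavelength's uniformly sampled PPG trace.
Quality annotations are carried as :class:`AnnotationSpan` intervals with the
three-level clean / okay / noisy scheme; fixed-length analysis windows are
:class:`Epoch` objects carrying a majority-vote label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

LABELS = ("clean", "okay", "noisy")
#: Order used for worst-label tie-breaking: higher index = worse quality.
LABEL_SEVERITY = {label: i for i, label in enumerate(LABELS)}

WAVELENGTHS = ("green", "red", "infrared")


@dataclass(frozen=True)
class AnnotationSpan:
    """A labeled time interval ``[start_s, end_s)`` within a record."""

    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(
                f"span must have start_s < end_s, got [{self.start_s}, {self.end_s}]"
            )
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class PpgRecord:
    """One wavelength's uniformly sampled PPG trace with metadata.

    Parameters
    ----------
    subject_id : str
    wavelength : str
        One of ``green``, ``red``, ``infrared``.
    fs : float
        Sampling rate in Hz.
    samples : ndarray
        The PPG signal, one value per sample.
    start_time_s : float
        Absolute time of the first sample.
    truth_spans : list of AnnotationSpan
        Ground-truth quality annotations (present for synthetic data).
    beat_times_s : ndarray or None
        Ground-truth systolic peak times (synthetic data only); used to
        validate beat detectors.
    nominal_hr_hz : float or None
        Nominal heart rate used by the generator (synthetic data only).
    """

    subject_id: str
    wavelength: str
    fs: float
    samples: np.ndarray
    start_time_s: float = 0.0
    truth_spans: list[AnnotationSpan] = field(default_factory=list)
    beat_times_s: np.ndarray | None = None
    nominal_hr_hz: float | None = None

    def __post_init__(self) -> None:
        if self.wavelength not in WAVELENGTHS:
            raise ValueError(
                f"wavelength must be one of {WAVELENGTHS}, got {self.wavelength!r}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def with_samples(self, samples: np.ndarray) -> "PpgRecord":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class Epoch:
    """A fixed-length analysis window cut from a record.

    ``label_fractions`` are the fractions of window time covered by each of
    the clean / okay / noisy annotations (in that order, summing to 1);
    ``label`` is their argmax with ties broken toward the worse quality.
    """

    subject_id: str
    wavelength: str
    start_s: float
    fs: float
    samples: np.ndarray
    label: str
    label_fractions: tuple[float, float, float]

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


def spans_to_sample_labels(
    spans: Sequence[AnnotationSpan], n_samples: int, fs: float
) -> np.ndarray:
    """Rasterize annotation spans to a per-sample severity array.

    Uncovered samples default to clean (severity 0). Where spans overlap the
    worse label wins.
    """
    out = np.zeros(n_samples, dtype=np.int8)
    for span in spans:
        i0 = max(0, int(round(span.start_s * fs)))
        i1 = min(n_samples, int(round(span.end_s * fs)))
        sev = LABEL_SEVERITY[span.label]
        np.maximum(out[i0:i1], sev, out=out[i0:i1])
    return out


def sample_labels_to_spans(labels: np.ndarray, fs: float) -> list[AnnotationSpan]:
    """Compress a per-sample severity array into ordered, disjoint spans."""
    if len(labels) == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(labels)]))
    return [
        AnnotationSpan(start_s=s / fs, end_s=e / fs, label=LABELS[labels[s]])
        for s, e in zip(starts, ends)
    ]
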