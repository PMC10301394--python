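"""Plain-text readers and writers for records, annotations and features.

One record is stored as a two-column CSV (``time_s,value``) plus a JSON
sidecar with subject id, wavelength, sampling rate and the annotation spans
as ``[start_s, end_s, label]`` triples.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .records import AnnotationSpan, Epoch, PpgRecord


def record_basename(record: PpgRecord) -> str:
    return f"{record.subject_id}_{record.wavelength}"


def write_record(record: PpgRecord, out_dir: str | Path) -> tuple[Path, Path]:
    """Write one record as CSV + JSON sidecar; returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = record_basename(record)
    csv_path = out_dir / f"{base}.csv"
    json_path = out_dir / f"{base}.json"

    t = record.start_time_s + np.arange(len(record.samples)) / record.fs
    pd.DataFrame({"time_s": t, "value": record.samples}).to_csv(csv_path, index=False)

    sidecar = {
        "subject_id": record.subject_id,
        "wavelength": record.wavelength,
        "fs": record.fs,
        "start_time_s": record.start_time_s,
        "truth_spans": [[s.start_s, s.end_s, s.label] for s in record.truth_spans],
    }
    if record.beat_times_s is not None:
        sidecar["beat_times_s"] = list(map(float, record.beat_times_s))
    if record.nominal_hr_hz is not None:
        sidecar["nominal_hr_hz"] = record.nominal_hr_hz
    json_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, json_path


def read_record(csv_path: str | Path) -> PpgRecord:
    """Read a record written by :func:`write_record`."""
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    frame = pd.read_csv(csv_path)
    beat_times = meta.get("beat_times_s")
    return PpgRecord(
        subject_id=meta["subject_id"],
        wavelength=meta["wavelength"],
        fs=float(meta["fs"]),
        samples=frame["value"].to_numpy(),
        start_time_s=float(meta.get("start_time_s", 0.0)),
        truth_spans=[AnnotationSpan(*span) for span in meta["truth_spans"]],
        beat_times_s=np.asarray(beat_times) if beat_times is not None else None,
        nominal_hr_hz=meta.get("nominal_hr_hz"),
    )


def read_cohort(data_dir: str | Path) -> list[PpgRecord]:
    return [read_record(p) for p in sorted(Path(data_dir).glob("*.csv"))]


def write_epoch_manifest(epochs: Iterable[Epoch], path: str | Path) -> Path:
    """Epoch manifest CSV: subject, wavelength, start, label, fractions."""
    rows = [
        {
            "subject_id": e.subject_id,
            "wavelength": e.wavelength,
            "start_s": e.start_s,
            "label": e.label,
            "frac_clean": e.label_fractions[0],
            "frac_okay": e.label_fractions[1],
            "frac_noisy": e.label_fractions[2],
        }
        for e in epochs
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
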