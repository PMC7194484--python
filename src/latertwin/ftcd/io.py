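"""Delimited-text readers and writers for the fTCD pipeline.

The raw-recording dialect is a delimited file (comma or tab, sniffed)
with a header row and columns ``time_s, left, right, marker`` plus an
optional ``trial_valid`` column; ``marker`` is nonzero at the onset
sample of each cue to speak.  A directory-of-files layout (one file per
subject, subject id from the file stem) mirrors deposited raw-data
archives; other export dialects can be adapted by passing a
``column_map``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ..exceptions import MalformedInputError
from .types import ProcessingConfig, SubjectLaterality, TrialEpoch, VelocityRecording

RAW_COLUMNS = ("time_s", "left", "right", "marker")


def read_recording_csv(
    path,
    subject_id: str | None = None,
    expected_rate: float | None = None,
    column_map: dict[str, str] | None = None,
) -> VelocityRecording:
    """Read one raw recording; the sample rate is inferred from the time
    column and cross-checked against ``expected_rate`` when given."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedInputError(f"{path.name}: missing columns {missing}")
    time = df["time_s"].to_numpy(dtype=float)
    if len(time) < 2:
        raise MalformedInputError(f"{path.name}: too few samples")
    fs = 1.0 / float(np.median(np.diff(time)))
    if expected_rate is not None and abs(fs - expected_rate) / expected_rate > 0.01:
        raise MalformedInputError(
            f"{path.name}: inferred rate {fs:.3f} Hz disagrees with "
            f"configured {expected_rate:.3f} Hz"
        )
    markers = np.flatnonzero(df["marker"].to_numpy() != 0)
    trial_valid = None
    if "trial_valid" in df.columns:
        trial_valid = df["trial_valid"].to_numpy()[markers].astype(bool)
    return VelocityRecording(
        subject_id=subject_id or path.stem,
        sample_rate=fs,
        time=time,
        left_velocity=df["left"].to_numpy(dtype=float),
        right_velocity=df["right"].to_numpy(dtype=float),
        marker_indices=markers,
        trial_valid=trial_valid,
    )


def read_recording_dir(
    directory, pattern: str = "*.csv", **kwargs
) -> list[VelocityRecording]:
    """One recording per file; subject ids come from file stems."""
    directory = Path(directory)
    files = sorted(directory.glob(pattern))
    if not files:
        raise MalformedInputError(f"no {pattern} files under {directory}")
    return [read_recording_csv(f, **kwargs) for f in files]


def write_recording_csv(rec: VelocityRecording, path) -> None:
    marker = np.zeros(len(rec.time), dtype=int)
    marker[rec.marker_indices] = 1
    df = pd.DataFrame(
        {
            "time_s": rec.time,
            "left": rec.left_velocity,
            "right": rec.right_velocity,
            "marker": marker,
        }
    )
    if rec.trial_valid is not None:
        tv = np.ones(len(rec.time), dtype=int)
        tv[rec.marker_indices] = rec.trial_valid.astype(int)
        df["trial_valid"] = tv
    df.to_csv(path, index=False, float_format="%.6f")


def trial_li_frame(
    per_subject: dict[str, Sequence[TrialEpoch]]
) -> pd.DataFrame:
    """Per-trial LI table mirroring an individual-trial-LIs CSV."""
    rows = []
    for sid, epochs in per_subject.items():
        for e in epochs:
            rows.append(
                {
                    "subject_id": sid,
                    "trial_index": e.trial_index,
                    "accepted": e.accepted,
                    "rejection_reason": e.rejection_reason,
                    "trial_li_mean": e.trial_li_mean,
                    "trial_li_peak": e.trial_li_peak,
                }
            )
    return pd.DataFrame(rows)


def write_trial_lis(per_subject: dict[str, Sequence[TrialEpoch]], path) -> None:
    trial_li_frame(per_subject).to_csv(path, index=False, float_format="%.6f")


def subjects_frame(subjects: Iterable[SubjectLaterality]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in subjects])


def write_subject_summaries(
    subjects: Iterable[SubjectLaterality],
    path,
    config: ProcessingConfig | None = None,
) -> None:
    """Subject-summary CSV with the processing configuration embedded as
    a JSON sidecar (``<path>.config.json``) for provenance."""
    path = Path(path)
    subjects_frame(subjects).to_csv(path, index=False, float_format="%.6f")
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".config.json")
        sidecar.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
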