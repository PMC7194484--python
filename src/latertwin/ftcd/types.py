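"""Domain types of the functional-transcranial-Doppler (fTCD) pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..exceptions import MalformedInputError

REJECTION_REASONS = ("none", "prolonged_dropout", "artifact", "behaviour")
EXCLUSION_REASONS = ("none", "too_few_trials", "outlier_5sd")


@dataclass
class PeriodOfInterest:
    """Post-cue window over which laterality indices are computed.

    The mean-based LI averages the left-minus-right difference over
    [start, end] seconds after the cue to speak; the peak-based LI
    averages over ±``peak_window_halfwidth`` around the largest absolute
    excursion in the same window (a 2 s window by default)."""

    start: float = 4.0
    end: float = 14.0
    peak_window_halfwidth: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise MalformedInputError("need 0 <= start < end")
        if self.peak_window_halfwidth <= 0:
            raise MalformedInputError("peak_window_halfwidth must be > 0")


@dataclass
class ProcessingConfig:
    """All knobs of the signal pipeline, with field-standard defaults.

    The epoch spans the 12 s silent-viewing period and the 10 s speaking
    period with margin; the baseline is the late silent-viewing interval
    just before the cue; normalized samples outside the artifact bounds
    reject the trial; heartbeats are detected on the summed channels with
    a minimum inter-beat interval of 0.33 s (<= 180 bpm, robust for child
    heart rates)."""

    epoch_start: float = -12.0
    epoch_end: float = 18.0
    baseline_start: float = -5.0
    baseline_end: float = 0.0
    artifact_lower: float = 60.0
    artifact_upper: float = 140.0
    min_beat_interval: float = 0.33
    dropout_threshold: float = 0.0
    poi: PeriodOfInterest = field(default_factory=PeriodOfInterest)
    min_trials: int = 12
    alpha: float = 0.05
    sd_limit: float = 5.0

    def __post_init__(self) -> None:
        if self.epoch_start >= self.epoch_end:
            raise MalformedInputError("epoch window is empty")
        if not (self.epoch_start <= self.baseline_start < self.baseline_end):
            raise MalformedInputError("baseline window must sit inside the epoch")
        if self.artifact_lower >= self.artifact_upper:
            raise MalformedInputError("artifact bounds are inverted")

    def to_dict(self) -> dict:
        return {
            "epoch_start": self.epoch_start,
            "epoch_end": self.epoch_end,
            "baseline_start": self.baseline_start,
            "baseline_end": self.baseline_end,
            "artifact_lower": self.artifact_lower,
            "artifact_upper": self.artifact_upper,
            "min_beat_interval": self.min_beat_interval,
            "dropout_threshold": self.dropout_threshold,
            "poi": {
                "start": self.poi.start,
                "end": self.poi.end,
                "peak_window_halfwidth": self.poi.peak_window_halfwidth,
            },
            "min_trials": self.min_trials,
            "alpha": self.alpha,
            "sd_limit": self.sd_limit,
        }


@dataclass
class VelocityRecording:
    """Bilateral blood-flow-velocity recording with speak-cue markers.

    ``marker_indices`` hold the onset sample of each cue to speak;
    ``trial_valid`` is the optional behavioural validity flag per marker.
    After :func:`~latertwin.ftcd.preprocess.preprocess_recording` the
    channels are heart-cycle integrated and rescaled to a recording-wide
    mean of 100 (% units), and ``dropout_intervals`` lists the sample
    ranges of prolonged (>= 2 sample) dropout."""

    subject_id: str
    sample_rate: float
    time: np.ndarray
    left_velocity: np.ndarray
    right_velocity: np.ndarray
    marker_indices: np.ndarray
    trial_valid: Optional[np.ndarray] = None
    normalized: bool = False
    dropout_intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.left_velocity = np.asarray(self.left_velocity, dtype=float)
        self.right_velocity = np.asarray(self.right_velocity, dtype=float)
        self.marker_indices = np.asarray(self.marker_indices, dtype=int)
        n = len(self.time)
        if not (len(self.left_velocity) == len(self.right_velocity) == n):
            raise MalformedInputError("channel lengths differ")
        if n < 2 or self.sample_rate <= 0:
            raise MalformedInputError("empty recording or invalid sample rate")
        dt = np.diff(self.time)
        if (dt <= 0).any() or np.ptp(dt) > 1e-3 / self.sample_rate + 1e-9:
            raise MalformedInputError("time grid must be strictly increasing and uniform")
        if abs(dt.mean() * self.sample_rate - 1.0) > 1e-3:
            raise MalformedInputError("sample_rate does not match the time grid")
        if len(self.marker_indices):
            if (np.diff(self.marker_indices) <= 0).any():
                raise MalformedInputError("markers must be strictly increasing")
            if self.marker_indices[0] < 0 or self.marker_indices[-1] >= n:
                raise MalformedInputError("markers fall outside the recording")
        if self.trial_valid is not None:
            self.trial_valid = np.asarray(self.trial_valid, dtype=bool)
            if len(self.trial_valid) != len(self.marker_indices):
                raise MalformedInputError("trial_valid must match the marker count")


@dataclass
class TrialEpoch:
    """One cue-aligned, normalized, baseline-corrected two-channel epoch.

    ``left_norm``/``right_norm`` are percentages of the channel mean with
    the baseline-window mean subtracted (accepted epochs only);
    ``diff = left_norm - right_norm`` in percentage points, positive when
    flow is greater on the left (left-lateralised)."""

    trial_index: int
    rel_time: np.ndarray
    left_norm: np.ndarray
    right_norm: np.ndarray
    diff: np.ndarray
    accepted: bool
    rejection_reason: str = "none"
    trial_li_mean: Optional[float] = None
    trial_li_peak: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rejection_reason not in REJECTION_REASONS:
            raise MalformedInputError(f"unknown reason {self.rejection_reason!r}")
        if self.accepted and self.rejection_reason != "none":
            raise MalformedInputError("accepted epochs carry no rejection reason")


@dataclass
class SubjectLaterality:
    """Per-subject laterality summary over accepted trials."""

    subject_id: str
    n_accepted: int
    li_mean: float = np.nan
    li_peak: float = np.nan
    se: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    se_peak: float = np.nan
    ci_peak_low: float = np.nan
    ci_peak_high: float = np.nan
    category: str = "bilateral"  # left | bilateral | right
    binary_typical: str = "atypical"  # typical | atypical
    li_odd: float = np.nan
    li_even: float = np.nan
    mean_left_flow: float = np.nan
    mean_right_flow: float = np.nan
    excluded: bool = False
    exclusion_reason: str = "none"

    def to_dict(self) -> dict:
        return dict(self.__dict__)
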