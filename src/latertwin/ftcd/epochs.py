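"""Epoching, artifact rejection, baseline correction and per-trial LIs."""

from __future__ import annotations

import logging

import numpy as np

from ..exceptions import MalformedInputError
from .types import PeriodOfInterest, ProcessingConfig, TrialEpoch, VelocityRecording

logger = logging.getLogger(__name__)


def epoch_and_reject(
    rec: VelocityRecording, cfg: ProcessingConfig | None = None
) -> list[TrialEpoch]:
    """Cut one cue-aligned epoch per marker and apply trial rejection.

    Rejection reasons, checked in order: ``prolonged_dropout`` (a flagged
    dropout interval overlaps the epoch), ``artifact`` (any normalized
    sample outside the configured bounds, or the epoch window runs off
    the recording edge), ``behaviour`` (the examiner's validity flag).
    Accepted epochs are baseline-corrected per channel by subtracting the
    channel's mean over the baseline window, making each channel's
    baseline mean exactly zero.
    """
    cfg = cfg or ProcessingConfig()
    if not rec.normalized:
        raise MalformedInputError("recording must be preprocessed first")
    fs = rec.sample_rate
    pre = int(round(-cfg.epoch_start * fs))
    post = int(round(cfg.epoch_end * fs))
    rel_time = np.arange(-pre, post + 1) / fs
    n = len(rec.time)
    epochs: list[TrialEpoch] = []
    for i, m in enumerate(rec.marker_indices):
        lo, hi = m - pre, m + post
        if lo < 0 or hi >= n:
            logger.warning(
                "subject %s trial %d: epoch window exceeds the recording; rejected",
                rec.subject_id, i,
            )
            epochs.append(
                TrialEpoch(
                    trial_index=i,
                    rel_time=rel_time,
                    left_norm=np.array([]),
                    right_norm=np.array([]),
                    diff=np.array([]),
                    accepted=False,
                    rejection_reason="artifact",
                )
            )
            continue
        left = rec.left_velocity[lo : hi + 1].copy()
        right = rec.right_velocity[lo : hi + 1].copy()
        reason = "none"
        if any(a <= hi and b >= lo for a, b in rec.dropout_intervals):
            reason = "prolonged_dropout"
        elif (
            (left < cfg.artifact_lower).any()
            or (left > cfg.artifact_upper).any()
            or (right < cfg.artifact_lower).any()
            or (right > cfg.artifact_upper).any()
        ):
            reason = "artifact"
        elif rec.trial_valid is not None and not rec.trial_valid[i]:
            reason = "behaviour"
        accepted = reason == "none"
        if accepted:
            bl = (rel_time >= cfg.baseline_start) & (rel_time < cfg.baseline_end)
            left = left - left[bl].mean()
            right = right - right[bl].mean()
        epochs.append(
            TrialEpoch(
                trial_index=i,
                rel_time=rel_time,
                left_norm=left,
                right_norm=right,
                diff=left - right,
                accepted=accepted,
                rejection_reason=reason,
            )
        )
    return epochs


def compute_trial_li(
    epoch: TrialEpoch, poi: PeriodOfInterest | None = None
) -> tuple[float, float]:
    """Mean-based and peak-based laterality index of one accepted epoch.

    Mean-based: the mean of the left-minus-right difference over the
    period of interest.  Peak-based: the mean over ±halfwidth around the
    sample of largest absolute difference in the period of interest
    (earliest sample on exact ties; the window is truncated at the POI
    edges).  Both share the sign convention positive = left > right.
    """
    poi = poi or PeriodOfInterest()
    if not epoch.accepted:
        raise MalformedInputError("trial LI is defined only for accepted epochs")
    t = epoch.rel_time
    sel = (t >= poi.start) & (t <= poi.end)
    if not sel.any():
        raise MalformedInputError("period of interest contains no samples")
    d = epoch.diff[sel]
    ts = t[sel]
    li_mean = float(d.mean())
    peak_pos = int(np.argmax(np.abs(d)))  # argmax returns the earliest tie
    t_star = ts[peak_pos]
    win = (ts >= t_star - poi.peak_window_halfwidth) & (
        ts <= t_star + poi.peak_window_halfwidth
    )
    li_peak = float(d[win].mean())
    epoch.trial_li_mean = li_mean
    epoch.trial_li_peak = li_peak
    return li_mean, li_peak
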