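"""Raw-signal cleaning: dropout handling, heart-cycle integration,
normalisation.

Doppler velocity traces are dominated by cardiac pulsatility.  Heart-cycle
integration removes it: beat onsets are detected on the summed left+right
channel, each channel's samples within a cardiac cycle are replaced by the
cycle's (time-weighted) mean, and the piecewise cycle means are resampled
back onto the original grid by linear interpolation between cycle
midpoints.  Each channel is then rescaled so its recording-wide mean is
100, making values percentages of mean flow and the pipeline invariant to
probe gain.

Dropout (velocity <= threshold, physiologically impossible) is repaired
when it affects a single sample — replaced by the mean of the flanking
samples — and flagged as a prolonged-dropout interval when it spans two or
more samples, so that epoching can reject the containing trial.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.signal import find_peaks

from ..exceptions import UnusableRecordingError
from .types import ProcessingConfig, VelocityRecording


def _dropout_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) index runs of True values."""
    runs = []
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return runs
    start = prev = idx[0]
    for i in idx[1:]:
        if i == prev + 1:
            prev = i
            continue
        runs.append((start, prev))
        start = prev = i
    runs.append((start, prev))
    return runs


def repair_dropouts(
    channel: np.ndarray, threshold: float = 0.0
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Interpolate single-sample dropouts; return prolonged intervals.

    A dropout sample has value <= ``threshold`` or is missing.  Isolated
    dropouts are replaced by the mean of the flanking samples; runs of two
    or more (and dropouts at the recording edges) are linearly bridged so
    integration stays finite, but their intervals are returned so the
    containing trial can be rejected."""
    x = np.asarray(channel, dtype=float).copy()
    bad = ~np.isfinite(x) | (x <= threshold)
    prolonged: list[tuple[int, int]] = []
    for start, end in _dropout_runs(bad):
        if start == end and 0 < start < len(x) - 1:
            x[start] = 0.5 * (x[start - 1] + x[start + 1])
        else:
            prolonged.append((start, end))
    if prolonged:
        good = ~bad
        if good.sum() < 2:
            raise UnusableRecordingError("recording is almost entirely dropout")
        idx = np.arange(len(x))
        x[bad] = np.interp(idx[bad], idx[good], x[good])
    return x, prolonged


def detect_beats(
    left: np.ndarray, right: np.ndarray, sample_rate: float, min_interval: float
) -> np.ndarray:
    """Beat-onset sample indices from peaks of the summed channels."""
    combined = left + right
    if np.ptp(combined) < 1e-9:
        raise UnusableRecordingError("flat signal: no detectable heartbeats")
    distance = max(1, int(round(min_interval * sample_rate)))
    prominence = 0.1 * np.std(combined)
    peaks, _ = find_peaks(combined, distance=distance, prominence=prominence)
    if len(peaks) < 3:
        raise UnusableRecordingError("fewer than 3 heartbeats detected")
    # sub-sample refinement: parabola through the peak and its neighbours,
    # so cycle boundaries are not snapped to the sample grid
    refined = peaks.astype(float)
    inner = (peaks > 0) & (peaks < len(combined) - 1)
    y0 = combined[peaks[inner] - 1]
    y1 = combined[peaks[inner]]
    y2 = combined[peaks[inner] + 1]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    refined[inner] += np.clip(shift, -0.5, 0.5)
    return refined


def integrate_cycles(channel: np.ndarray, beats: np.ndarray) -> np.ndarray:
    """Replace cardiac cycles by their means, resampled to the full grid.

    Each cycle's time-weighted mean is the trapezoid integral of the
    (linearly interpolated) channel between consecutive beat onsets —
    which may sit between samples — divided by the cycle length.  Cycle
    means are anchored at cycle midpoints and linearly interpolated back
    onto the grid (clamped beyond the first/last cycle)."""
    x = np.asarray(channel, dtype=float)
    beats = np.asarray(beats, dtype=float)
    idx = np.arange(len(x), dtype=float)
    # cumulative trapezoid integral of the linear interpolant at samples
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (x[1:] + x[:-1]))])

    def integral_at(pos: np.ndarray) -> np.ndarray:
        i = np.clip(np.floor(pos).astype(int), 0, len(x) - 2)
        frac = pos - i
        # integral of the linear segment from i to i+frac
        seg = frac * x[i] + 0.5 * frac**2 * (x[i + 1] - x[i])
        return cum[i] + seg

    a, b = beats[:-1], beats[1:]
    means = (integral_at(b) - integral_at(a)) / (b - a)
    mids = 0.5 * (a + b)
    return np.interp(idx, mids, means)


def preprocess_recording(
    rec: VelocityRecording, cfg: ProcessingConfig | None = None
) -> VelocityRecording:
    """Clean and normalise a raw recording.

    Returns a new :class:`VelocityRecording` whose channels are dropout
    repaired, heart-cycle integrated and rescaled to a recording-wide
    mean of 100; prolonged-dropout intervals are recorded on the result
    for downstream trial rejection.  Heart-cycle integration preserves
    each channel's overall mean to within 0.5%.
    """
    cfg = cfg or ProcessingConfig()
    left, bad_left = repair_dropouts(rec.left_velocity, cfg.dropout_threshold)
    right, bad_right = repair_dropouts(rec.right_velocity, cfg.dropout_threshold)
    beats = detect_beats(left, right, rec.sample_rate, cfg.min_beat_interval)
    left_i = integrate_cycles(left, beats)
    right_i = integrate_cycles(right, beats)
    out_channels = []
    for ch in (left_i, right_i):
        m = ch.mean()
        if m <= 0:
            raise UnusableRecordingError("non-positive mean velocity after integration")
        out_channels.append(100.0 * ch / m)
    return replace(
        rec,
        left_velocity=out_channels[0],
        right_velocity=out_channels[1],
        normalized=True,
        dropout_intervals=sorted(set(bad_left) | set(bad_right)),
    )
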