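"""Synthetic fTCD sessions with known ground-truth laterality.

The generator emulates the animation-description paradigm: on each trial
the child silently views a clip for 12 s, then a cue starts a 10 s
speaking period.  A session is a continuous two-channel velocity trace
with

* cardiac pulsatility — beat-to-beat jittered cycles with a systolic
  bump, zero-mean within each cycle so cycle means track the slow
  components exactly;
* slow multiplicative AR(1) drift per channel;
* multiplicative white noise;
* a task-evoked bilateral activation plus a lateralised differential:
  the left channel gains +delta/2 percent and the right −delta/2 percent
  times a gamma-shaped activation curve scaled to unit mean over the
  period of interest, so the normalized POI-mean difference equals
  ``response_delta`` exactly in expectation;
* optional injected single-sample dropouts, prolonged dropouts, artifact
  spikes and behaviourally invalid trials, all recorded in the truth log
  so pipeline rejection counts can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ..exceptions import MalformedInputError
from ..ftcd.types import VelocityRecording


@dataclass
class DopplerSimConfig:
    n_trials: int = 30
    sample_rate: float = 25.0
    heart_rate_mean: float = 95.0  # bpm, child range
    heart_rate_sd: float = 8.0
    baseline_left: float = 55.0  # cm/s
    baseline_right: float = 50.0
    pulse_amplitude: float = 0.25  # fraction of baseline
    response_delta: float = 2.0  # percentage points, the true LI
    response_shape: tuple[float, float] = (4.0, 2.0)  # gamma shape, scale (s)
    bilateral_gain: float = 3.0  # shared activation, % at shape peak scale
    noise_sd: float = 2.0  # % of instantaneous level, per sample
    drift_coef: float = 0.995  # AR(1) coefficient per sample
    drift_sd: float = 0.01  # stationary SD (fraction)
    brief_dropout_prob: float = 0.0  # per trial, single-sample dropout
    dropout_prob: float = 0.0  # per trial, prolonged dropout
    artifact_prob: float = 0.0  # per trial, amplitude spike
    behaviour_invalid_prob: float = 0.0
    lead_in: float = 20.0  # s before the first cue
    inter_trial: float = 35.0  # cue-to-cue spacing, s
    tail: float = 20.0
    poi: tuple[float, float] = (4.0, 14.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.brief_dropout_prob,
            self.dropout_prob,
            self.artifact_prob,
            self.behaviour_invalid_prob,
        ):
            if not (0.0 <= p <= 1.0):
                raise MalformedInputError("probabilities must lie in [0, 1]")
        if self.heart_rate_mean <= 0:
            raise MalformedInputError("heart rate must be positive")
        if self.inter_trial < 30.0:
            raise MalformedInputError(
                "inter-trial spacing shorter than the epoch window"
            )
        if self.lead_in < 12.0 or self.tail < 18.0:
            raise MalformedInputError("lead-in/tail too short for the epoch window")


@dataclass
class DopplerTruth:
    """Ground-truth log emitted with every simulated session."""

    true_li: float
    beat_onsets: np.ndarray  # sample indices
    cycle_means_left: np.ndarray
    cycle_means_right: np.ndarray
    cycle_mid_idx: np.ndarray
    dropout_trials: list = field(default_factory=list)
    brief_dropout_trials: list = field(default_factory=list)
    artifact_trials: list = field(default_factory=list)
    invalid_trials: list = field(default_factory=list)

    @property
    def n_injected_rejections(self) -> int:
        return len(
            set(self.dropout_trials) | set(self.artifact_trials) | set(self.invalid_trials)
        )


def activation_curve(
    rel_t: np.ndarray, shape: float, scale: float, poi: tuple[float, float]
) -> np.ndarray:
    """Gamma-shaped activation (rise peaking ~6–8 s after the cue, back to
    baseline by ~17 s), scaled to unit mean over the period of interest."""
    s = stats.gamma.pdf(np.clip(rel_t, 0, None), a=shape, scale=scale)
    s[rel_t < 0] = 0.0
    sel = (rel_t >= poi[0]) & (rel_t <= poi[1])
    norm = s[sel].mean()
    if norm <= 0:
        raise MalformedInputError("activation curve vanishes over the POI")
    return s / norm


def simulate_doppler_session(
    cfg: DopplerSimConfig, subject_id: str = "sim"
) -> tuple[VelocityRecording, DopplerTruth]:
    """Generate one session; bit-reproducible for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate
    duration = cfg.lead_in + (cfg.n_trials - 1) * cfg.inter_trial + cfg.tail
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    cue_times = cfg.lead_in + cfg.inter_trial * np.arange(cfg.n_trials)
    markers = np.round(cue_times * fs).astype(int)

    # --- cardiac cycles ---------------------------------------------------
    mean_iv = 60.0 / cfg.heart_rate_mean
    iv_sd = 60.0 * cfg.heart_rate_sd / cfg.heart_rate_mean**2
    beats = [0.0]
    while beats[-1] < duration + mean_iv:
        beats.append(beats[-1] + max(0.45, rng.normal(mean_iv, iv_sd)))
    beat_idx = np.round(np.array(beats) * fs).astype(int)
    beat_idx = beat_idx[beat_idx < n]
    beat_idx = np.unique(beat_idx)

    # systolic bump, made zero-mean within each cycle's samples
    pulse = np.zeros(n)
    for a, b in zip(beat_idx[:-1], beat_idx[1:]):
        phase = (np.arange(a, b) - a) / max(b - a, 1)
        w = np.exp(-(((phase - 0.2) / 0.12) ** 2))
        pulse[a:b] = w - w.mean()
    pulse *= cfg.pulse_amplitude

    # --- slow components --------------------------------------------------
    innov_sd = cfg.drift_sd * np.sqrt(1 - cfg.drift_coef**2)
    drift = np.empty((2, n))
    for ch in range(2):
        d = np.empty(n)
        d[0] = rng.normal(0, cfg.drift_sd)
        eps = rng.normal(0, innov_sd, n - 1)
        for i in range(1, n):
            d[i] = cfg.drift_coef * d[i - 1] + eps[i - 1]
        drift[ch] = d

    shape_grid = activation_curve(
        np.arange(-int(12 * fs), int(18 * fs) + 1) / fs,
        cfg.response_shape[0],
        cfg.response_shape[1],
        cfg.poi,
    )
    gain = np.zeros((2, n))  # task-evoked % change per channel
    half = cfg.response_delta / 2.0
    for m in markers:
        lo = m - int(12 * fs)
        hi = lo + len(shape_grid)
        seg = slice(max(lo, 0), min(hi, n))
        src = slice(seg.start - lo, seg.stop - lo)
        gain[0, seg] += (cfg.bilateral_gain + half) * shape_grid[src]
        gain[1, seg] += (cfg.bilateral_gain - half) * shape_grid[src]
    # centre the gain over the recording: normalisation to mean 100 then
    # leaves the baseline-corrected difference at delta·s(t) exactly
    gain -= gain.mean(axis=1, keepdims=True)

    bases = (cfg.baseline_left, cfg.baseline_right)
    channels = []
    for ch in range(2):
        slow = (1.0 + drift[ch]) * (1.0 + gain[ch] / 100.0)
        noise = rng.normal(0.0, cfg.noise_sd / 100.0, n)
        channels.append(bases[ch] * slow * (1.0 + pulse) * (1.0 + noise))
    left, right = channels

    # per-cycle means of the clean trace: the oracle for integration tests
    mids, ml, mr = [], [], []
    for a, b in zip(beat_idx[:-1], beat_idx[1:]):
        mids.append(0.5 * (a + b - 1))
        ml.append(left[a:b].mean())
        mr.append(right[a:b].mean())

    # --- injected events --------------------------------------------------
    truth = DopplerTruth(
        true_li=cfg.response_delta,
        beat_onsets=beat_idx,
        cycle_means_left=np.array(ml),
        cycle_means_right=np.array(mr),
        cycle_mid_idx=np.array(mids),
    )
    trial_valid = np.ones(cfg.n_trials, dtype=bool)
    for k, m in enumerate(markers):
        if rng.random() < cfg.brief_dropout_prob:
            left[m + int(2 * fs)] = 0.0
            truth.brief_dropout_trials.append(k)
        if rng.random() < cfg.dropout_prob:
            start = m + int(rng.uniform(1.0, 9.0) * fs)
            left[start : start + 5] = 0.0
            truth.dropout_trials.append(k)
        elif rng.random() < cfg.artifact_prob:
            start = m + int(rng.uniform(2.0, 8.0) * fs)
            run = int(0.8 * fs)
            left[start : start + run] *= 1.7
            truth.artifact_trials.append(k)
        elif rng.random() < cfg.behaviour_invalid_prob:
            trial_valid[k] = False
            truth.invalid_trials.append(k)

    rec = VelocityRecording(
        subject_id=subject_id,
        sample_rate=fs,
        time=t,
        left_velocity=left,
        right_velocity=right,
        marker_indices=markers,
        trial_valid=trial_valid,
    )
    return rec, truth
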