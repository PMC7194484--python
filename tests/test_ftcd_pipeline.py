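"""Signal pipeline: dropout repair, heart-cycle integration, epoching,
trial rejection and per-trial laterality indices."""

import numpy as np
import pytest

from latertwin.exceptions import MalformedInputError, UnusableRecordingError
from latertwin.ftcd import (
    PeriodOfInterest,
    ProcessingConfig,
    TrialEpoch,
    VelocityRecording,
    compute_trial_li,
    epoch_and_reject,
    preprocess_recording,
    process_recording,
)
from latertwin.ftcd.preprocess import repair_dropouts
from latertwin.simulate import DopplerSimConfig, simulate_doppler_session


def _recording(left, right, fs=25.0, markers=(), **kwargs):
    n = len(left)
    return VelocityRecording(
        subject_id="t",
        sample_rate=fs,
        time=np.arange(n) / fs,
        left_velocity=left,
        right_velocity=right,
        marker_indices=np.asarray(markers, dtype=int),
        **kwargs,
    )


class TestPreprocess:
    def test_sinusoidal_pulsatility_removed(self):
        """A constant 50 cm/s flow with pure 1.5 Hz pulsatility integrates
        to a constant normalized 100 over the recording interior."""
        fs = 25.0
        t = np.arange(0, 60, 1 / fs)
        pulse = 10 * np.sin(2 * np.pi * 1.5 * t)
        rec = _recording(50 + pulse, 50 + 0.8 * pulse, fs=fs)
        out = preprocess_recording(rec)
        interior = slice(int(2 * fs), int(58 * fs))
        assert np.all(np.abs(out.left_velocity[interior] - 100.0) < 0.5)
        assert np.all(np.abs(out.right_velocity[interior] - 100.0) < 0.5)

    def test_overall_mean_preserved(self, clean_session):
        rec, _ = clean_session
        out = preprocess_recording(rec)
        for raw, norm in (
            (rec.left_velocity, out.left_velocity),
            (rec.right_velocity, out.right_velocity),
        ):
            # integration preserves the channel mean to within 0.5%
            assert norm.mean() == pytest.approx(100.0, rel=0.005)

    def test_single_dropout_interpolated(self):
        x = np.full(100, 50.0)
        x[40], x[42] = 48.0, 52.0
        x[41] = 0.0
        repaired, prolonged = repair_dropouts(x)
        assert repaired[41] == pytest.approx(50.0)
        assert prolonged == []

    def test_prolonged_dropout_flagged(self):
        x = np.full(200, 50.0)
        x[100:104] = 0.0
        _, prolonged = repair_dropouts(x)
        assert prolonged == [(100, 103)]

    def test_flat_signal_unusable(self):
        rec = _recording(np.full(500, 50.0), np.full(500, 50.0))
        with pytest.raises(UnusableRecordingError):
            preprocess_recording(rec)

    def test_nonuniform_grid_rejected(self):
        t = np.arange(100) / 25.0
        t[50] += 0.01
        with pytest.raises(MalformedInputError):
            VelocityRecording(
                "t", 25.0, t, np.ones(100), np.ones(100), np.array([], dtype=int)
            )

    def test_cycle_means_match_generator_truth(self):
        """Integrated trace equals the generator's stored per-cycle means
        at cycle midpoints, up to interpolation at those exact samples
        (steady heart rate, so detection phase cannot alias the jitter)."""
        cfg = DopplerSimConfig(
            n_trials=10, response_delta=2.0, noise_sd=0.0, drift_sd=0.0,
            heart_rate_sd=0.0, seed=55,
        )
        rec, truth = simulate_doppler_session(cfg)
        out = preprocess_recording(rec)
        mean_left = rec.left_velocity.mean()
        mids = truth.cycle_mid_idx[5:-5]
        expected = 100.0 * truth.cycle_means_left[5:-5] / mean_left
        got = np.interp(mids, np.arange(len(out.left_velocity)), out.left_velocity)
        np.testing.assert_allclose(got, expected, rtol=2e-3)

    def test_gain_invariance(self, clean_session):
        """Scaling both raw channels by any gamma > 0 leaves the
        normalized pipeline output unchanged."""
        rec, _ = clean_session
        out1 = preprocess_recording(rec)
        scaled = _recording(
            3.7 * rec.left_velocity,
            3.7 * rec.right_velocity,
            fs=rec.sample_rate,
            markers=rec.marker_indices,
        )
        out2 = preprocess_recording(scaled)
        np.testing.assert_allclose(out2.left_velocity, out1.left_velocity, rtol=1e-9)


class TestEpochs:
    def test_rejection_counting(self, noisy_session):
        """Rejection reasons tally exactly with the generator's injection
        log (dropout, artifact, behaviour)."""
        rec, truth = noisy_session
        epochs, _ = process_recording(rec)
        reasons = {}
        for e in epochs:
            reasons.setdefault(e.rejection_reason, []).append(e.trial_index)
        assert sorted(reasons.get("prolonged_dropout", [])) == sorted(truth.dropout_trials)
        assert sorted(reasons.get("artifact", [])) == sorted(truth.artifact_trials)
        assert sorted(reasons.get("behaviour", [])) == sorted(truth.invalid_trials)
        n_rejected = sum(not e.accepted for e in epochs)
        assert n_rejected == truth.n_injected_rejections

    def test_baseline_mean_exactly_zero(self, clean_session):
        rec, _ = clean_session
        cfg = ProcessingConfig()
        clean = preprocess_recording(rec, cfg)
        epochs = epoch_and_reject(clean, cfg)
        for e in epochs:
            if not e.accepted:
                continue
            bl = (e.rel_time >= cfg.baseline_start) & (e.rel_time < cfg.baseline_end)
            assert e.left_norm[bl].mean() == pytest.approx(0.0, abs=1e-10)
            assert e.right_norm[bl].mean() == pytest.approx(0.0, abs=1e-10)

    def test_marker_near_edge_rejected_as_artifact(self):
        fs = 25.0
        t = np.arange(0, 40, 1 / fs)
        pulse = 10 * np.sin(2 * np.pi * 1.5 * t)
        rec = _recording(50 + pulse, 50 + pulse, fs=fs, markers=[int(2 * fs)])
        clean = preprocess_recording(rec)
        epochs = epoch_and_reject(clean)
        assert len(epochs) == 1
        assert not epochs[0].accepted
        assert epochs[0].rejection_reason == "artifact"


def _epoch_from_diff(rel_time, diff):
    return TrialEpoch(
        trial_index=0,
        rel_time=rel_time,
        left_norm=diff / 2,
        right_norm=-diff / 2,
        diff=diff,
        accepted=True,
    )


class TestTrialLI:
    def test_constant_difference(self):
        t = np.arange(-12, 18.01, 0.04)
        li_mean, li_peak = compute_trial_li(_epoch_from_diff(t, np.full_like(t, 2.0)))
        assert li_mean == pytest.approx(2.0)
        assert li_peak == pytest.approx(2.0)

    def test_sign_flip_with_tie_break(self):
        """+3 on [4,9), −3 on [9,14]: the mean cancels; the peak tie is
        broken to the earliest sample, giving +3."""
        t = np.arange(-12, 18.0001, 0.04)
        diff = np.zeros_like(t)
        diff[(t >= 4) & (t < 9)] = 3.0
        diff[(t >= 9) & (t <= 14)] = -3.0
        li_mean, li_peak = compute_trial_li(_epoch_from_diff(t, diff))
        assert li_mean == pytest.approx(0.0, abs=0.02)
        assert li_peak == pytest.approx(3.0)

    def test_sine_against_grid_oracle(self):
        """Half-sine difference wave: compare against direct numerical
        evaluation on the sampled grid."""
        fs = 25.0
        t = np.arange(-12 * fs, 18 * fs + 1) / fs
        diff = np.where(
            (t >= 4) & (t <= 14), np.sin(np.pi * (t - 4) / 10.0), 0.0
        )
        li_mean, li_peak = compute_trial_li(_epoch_from_diff(t, diff))
        # oracle: brute-force scan over the sampled grid
        sel = (t >= 4) & (t <= 14)
        d, ts = diff[sel], t[sel]
        exp_mean = d.mean()
        i = np.argmax(np.abs(d))
        win = (ts >= ts[i] - 1) & (ts <= ts[i] + 1)
        exp_peak = d[win].mean()
        assert li_mean == pytest.approx(exp_mean, abs=1e-9)
        assert li_peak == pytest.approx(exp_peak, abs=1e-9)

    def test_empty_poi_signalled(self):
        t = np.arange(-2, 2, 0.04)
        with pytest.raises(MalformedInputError):
            compute_trial_li(_epoch_from_diff(t, np.zeros_like(t)),
                             PeriodOfInterest(4, 14))


class TestGroundTruthRecovery:
    def test_noise_free_delta_recovered(self, clean_session):
        rec, truth = clean_session
        _, subject = process_recording(rec)
        assert subject.li_mean == pytest.approx(truth.true_li, rel=0.01)
        assert subject.category == "left"

    def test_sign_equivariance(self):
        """Flipping the sign of the injected response flips the subject's
        category left <-> right with the same magnitude."""
        out = {}
        for sign in (+1, -1):
            cfg = DopplerSimConfig(
                n_trials=16, response_delta=sign * 2.0, noise_sd=0.0,
                drift_sd=0.0, seed=77,
            )
            rec, _ = simulate_doppler_session(cfg)
            _, subject = process_recording(rec)
            out[sign] = subject
        assert out[1].category == "left"
        assert out[-1].category == "right"
        assert out[-1].li_mean == pytest.approx(-out[1].li_mean, rel=1e-6)

    def test_mean_peak_sign_agreement_monophasic(self, clean_session):
        """With a single-signed difference wave, mean- and peak-based LIs
        agree in sign for every accepted trial."""
        rec, _ = clean_session
        epochs, _ = process_recording(rec)
        for e in epochs:
            if e.accepted:
                assert np.sign(e.trial_li_mean) == np.sign(e.trial_li_peak)
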