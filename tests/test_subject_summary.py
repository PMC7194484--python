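"""Subject-level laterality summaries, exclusions and reliability."""

import numpy as np
import pytest
from scipy import stats

from latertwin.exceptions import DegenerateDataError
from latertwin.ftcd import (
    apply_sample_exclusions,
    process_recording,
    split_half_reliability,
    summarize_trial_lis,
)
from latertwin.simulate import DopplerSimConfig, simulate_doppler_session


class TestSummarize:
    def test_zero_variance_trials(self):
        s = summarize_trial_lis("s", [2.5] * 16)
        assert s.li_mean == 2.5
        assert s.se == 0.0
        assert s.category == "left"
        assert not s.excluded

    def test_t_interval_oracle(self):
        """20 trial LIs with mean 0.1 and sample SD 2.0: the t-based CI
        spans zero, so the subject is bilateral."""
        # constants with exact mean 0.1 and sample SD 2.0
        base = np.array([-1.0] * 10 + [1.0] * 10)
        vals = 0.1 + base * 2.0 / base.std(ddof=1)
        assert vals.mean() == pytest.approx(0.1)
        assert vals.std(ddof=1) == pytest.approx(2.0)
        s = summarize_trial_lis("s", vals)
        se = 2.0 / np.sqrt(20)
        assert s.se == pytest.approx(se, abs=1e-12)  # 0.4472...
        tq = stats.t.ppf(0.975, 19)
        assert s.ci_low == pytest.approx(0.1 - tq * se, abs=1e-12)
        assert s.ci_high == pytest.approx(0.1 + tq * se, abs=1e-12)
        assert s.category == "bilateral"

    def test_too_few_trials_excluded(self):
        s = summarize_trial_lis("s", [2.0] * 11)
        assert s.excluded and s.exclusion_reason == "too_few_trials"

    def test_single_trial_se_undefined_and_excluded(self):
        s = summarize_trial_lis("s", [2.0])
        assert np.isnan(s.se)
        assert s.excluded

    def test_binary_typical_follows_peak_ci(self):
        """Typical only when the peak-based CI lies entirely above zero."""
        up = summarize_trial_lis("a", [2.0 + 0.01 * i for i in range(16)])
        assert up.binary_typical == "typical"
        mixed = summarize_trial_lis(
            "b", [2.0] * 16, li_peak_trials=[(-1) ** i * 3.0 for i in range(16)]
        )
        assert mixed.category == "left"  # mean-based CI above zero
        assert mixed.binary_typical == "atypical"  # peak CI spans zero

    def test_odd_even_split_in_presentation_order(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0] * 3  # 18 trials
        s = summarize_trial_lis("s", vals)
        assert s.li_odd == pytest.approx(np.mean(vals[0::2]))
        assert s.li_even == pytest.approx(np.mean(vals[1::2]))


class TestExclusions:
    @staticmethod
    def _cohort(lis):
        return [summarize_trial_lis(f"s{i}", [v] * 16) for i, v in enumerate(lis)]

    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(1)
        lis = list(rng.normal(2.0, 1.0, 100))
        mu, sd = np.mean(lis), np.std(lis, ddof=1)
        lis.append(mu + 8 * sd)
        out = apply_sample_exclusions(self._cohort(lis), sd_limit=5)
        flagged = [s.subject_id for s in out if s.exclusion_reason == "outlier_5sd"]
        assert flagged == ["s100"]

    def test_no_outliers_identity(self):
        rng = np.random.default_rng(2)
        cohort = self._cohort(rng.normal(2.0, 1.0, 50))
        out = apply_sample_exclusions(cohort)
        assert [s.excluded for s in out] == [False] * 50

    def test_two_planted_outliers_zscore_oracle(self):
        rng = np.random.default_rng(3)
        lis = np.concatenate([rng.normal(0, 1, 200), [0.0, 0.0]])
        mu, sd = lis[:-2].mean(), None
        # plant at +-6 SD of the full first-pass sample
        full = lis.copy()
        m, s = full.mean(), full.std(ddof=1)
        lis[-2] = m + 6 * s
        lis[-1] = m - 6 * s
        out = apply_sample_exclusions(self._cohort(lis), sd_limit=5)
        z = (lis - lis.mean()) / lis.std(ddof=1)  # direct z-score oracle
        expect = {f"s{i}" for i in np.flatnonzero(np.abs(z) > 5)}
        got = {s_.subject_id for s_ in out if s_.exclusion_reason == "outlier_5sd"}
        assert got == expect
        assert got == {"s200", "s201"}


class TestReliability:
    @staticmethod
    def _subjects_from_halves(odd, even):
        subs = []
        for i, (o, e) in enumerate(zip(odd, even)):
            s = summarize_trial_lis(f"s{i}", [0.0] * 16)
            s.li_odd, s.li_even = o, e
            subs.append(s)
        return subs

    def test_identical_halves(self):
        odd = np.linspace(-1, 3, 10)
        r, sb = split_half_reliability(self._subjects_from_halves(odd, odd))
        assert r == pytest.approx(1.0)
        assert sb == pytest.approx(1.0)

    def test_antisymmetric_halves(self):
        odd = np.linspace(-1, 3, 10)
        r, _ = split_half_reliability(self._subjects_from_halves(odd, -odd))
        assert r == pytest.approx(-1.0)

    def test_zero_variance_signalled(self):
        with pytest.raises(DegenerateDataError):
            split_half_reliability(
                self._subjects_from_halves(np.zeros(5), np.arange(5.0))
            )

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_simulated_cohort_matches_closed_form(self, seed):
        """Per-trial noise chosen so the half-vs-half correlation of a
        24-trial session is 0.85: sigma_s^2 / (sigma_s^2 + 2 sigma_n^2 / n).
        The observed split-half r over 280 subjects sits within sampling
        error of that closed-form value."""
        n_sub, n_trials, target = 280, 24, 0.85
        sigma_s = 1.5
        sigma_n = np.sqrt((1 / target - 1) * n_trials / 2) * sigma_s
        rng = np.random.default_rng(seed)
        subs = []
        for i in range(n_sub):
            true_li = rng.normal(2.0, sigma_s)
            trials = true_li + rng.normal(0, sigma_n, n_trials)
            subs.append(summarize_trial_lis(f"s{i}", trials))
        r, sb = split_half_reliability(subs)
        assert r == pytest.approx(target, abs=0.04)
        assert sb > r  # full-length correction only raises the estimate


class TestCohortLevel:
    def test_mean_vs_peak_li_strongly_correlated(self):
        """Across subjects with heterogeneous response shapes the mean-
        and peak-based LIs correlate strongly (r > 0.9)."""
        rng = np.random.default_rng(31)
        li_mean, li_peak = [], []
        for i in range(40):
            cfg = DopplerSimConfig(
                n_trials=12,
                response_delta=float(rng.normal(2.0, 2.0)),
                response_shape=(float(rng.uniform(3, 5)), float(rng.uniform(1.5, 2.5))),
                noise_sd=1.0,
                seed=1000 + i,
            )
            rec, _ = simulate_doppler_session(cfg)
            _, s = process_recording(rec)
            li_mean.append(s.li_mean)
            li_peak.append(s.li_peak)
        r = np.corrcoef(li_mean, li_peak)[0, 1]
        assert r > 0.9

    def test_category_ci_coherence(self):
        """category = left implies the mean-based CI lower bound > 0 (and
        symmetrically for right) across a simulated cohort."""
        rng = np.random.default_rng(41)
        for i in range(30):
            trials = rng.normal(rng.normal(0, 1.5), 2.0, 16)
            s = summarize_trial_lis(f"s{i}", trials)
            if s.category == "left":
                assert s.ci_low > 0
            elif s.category == "right":
                assert s.ci_high < 0
            else:
                assert s.ci_low <= 0 <= s.ci_high
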