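"""Per-subject laterality summaries, cohort exclusions, reliability.

The subject LI is the mean of accepted per-trial LIs; its standard error
is the sample SD of trial LIs over the square root of the trial count,
and the confidence interval uses the Student-t quantile with n−1 degrees
of freedom (trial counts are small, 12–30).  Laterality category follows
the mean-based CI: left if it lies above zero, right if below, bilateral
if it spans zero.  The typical/atypical binary code follows the
peak-based CI: typical only when that interval lies entirely above zero.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
from scipy import stats

from ..exceptions import DegenerateDataError, MalformedInputError
from .epochs import compute_trial_li
from .types import PeriodOfInterest, SubjectLaterality, TrialEpoch


def _ci(values: np.ndarray, alpha: float) -> tuple[float, float, float]:
    n = len(values)
    se = float(values.std(ddof=1) / np.sqrt(n))
    tq = float(stats.t.ppf(1 - alpha / 2, n - 1))
    m = float(values.mean())
    return se, m - tq * se, m + tq * se


def summarize_trial_lis(
    subject_id: str,
    li_mean_trials: Sequence[float],
    li_peak_trials: Sequence[float] | None = None,
    mean_left_flow: float = np.nan,
    mean_right_flow: float = np.nan,
    min_trials: int = 12,
    alpha: float = 0.05,
) -> SubjectLaterality:
    """Build the subject summary from per-trial LI values.

    This is the statistical core of :func:`summarize_subject`, usable
    directly when trial LIs come from an external table (e.g. a deposited
    per-trial CSV)."""
    li = np.asarray(li_mean_trials, dtype=float)
    lp = np.asarray(
        li_peak_trials if li_peak_trials is not None else li_mean_trials, dtype=float
    )
    if len(li) != len(lp):
        raise MalformedInputError("mean and peak trial LI lengths differ")
    n = len(li)
    out = SubjectLaterality(subject_id=subject_id, n_accepted=n)
    out.mean_left_flow = mean_left_flow
    out.mean_right_flow = mean_right_flow
    if n == 0:
        out.excluded = True
        out.exclusion_reason = "too_few_trials"
        return out
    out.li_mean = float(li.mean())
    out.li_peak = float(lp.mean())
    if n >= 2:
        out.se, out.ci_low, out.ci_high = _ci(li, alpha)
        out.se_peak, out.ci_peak_low, out.ci_peak_high = _ci(lp, alpha)
        if out.ci_low > 0:
            out.category = "left"
        elif out.ci_high < 0:
            out.category = "right"
        else:
            out.category = "bilateral"
        out.binary_typical = "typical" if out.ci_peak_low > 0 else "atypical"
    # odd/even split over accepted trials in presentation order (1st, 3rd, ...)
    out.li_odd = float(li[0::2].mean())
    out.li_even = float(li[1::2].mean()) if n >= 2 else np.nan
    if n < min_trials:
        out.excluded = True
        out.exclusion_reason = "too_few_trials"
    return out


def summarize_subject(
    epochs: Sequence[TrialEpoch],
    poi: PeriodOfInterest | None = None,
    min_trials: int = 12,
    alpha: float = 0.05,
    subject_id: str = "",
) -> SubjectLaterality:
    """Summarise one subject's epochs into a :class:`SubjectLaterality`.

    Trial LIs are computed on demand for accepted epochs; mean left/right
    flow are the baseline-corrected normalized channel means over the
    period of interest, averaged across accepted trials.  Subjects with
    fewer than ``min_trials`` accepted trials are excluded."""
    poi = poi or PeriodOfInterest()
    accepted = [e for e in epochs if e.accepted]
    li_mean, li_peak, lflow, rflow = [], [], [], []
    for e in accepted:
        if e.trial_li_mean is None or e.trial_li_peak is None:
            compute_trial_li(e, poi)
        li_mean.append(e.trial_li_mean)
        li_peak.append(e.trial_li_peak)
        sel = (e.rel_time >= poi.start) & (e.rel_time <= poi.end)
        lflow.append(float(e.left_norm[sel].mean()))
        rflow.append(float(e.right_norm[sel].mean()))
    return summarize_trial_lis(
        subject_id=subject_id,
        li_mean_trials=li_mean,
        li_peak_trials=li_peak,
        mean_left_flow=float(np.mean(lflow)) if lflow else np.nan,
        mean_right_flow=float(np.mean(rflow)) if rflow else np.nan,
        min_trials=min_trials,
        alpha=alpha,
    )


def apply_sample_exclusions(
    subjects: Sequence[SubjectLaterality], sd_limit: float = 5.0
) -> list[SubjectLaterality]:
    """Single-pass outlier exclusion on the mean-based LI.

    The mean and SD are computed once over currently non-excluded
    subjects; anyone more than ``sd_limit`` SDs from that mean is marked
    excluded with reason ``outlier_5sd``.  Pair-level propagation (also
    dropping the cotwin) is the caller's responsibility when building the
    twin table."""
    active = [s for s in subjects if not s.excluded]
    if len(active) < 3:
        raise DegenerateDataError("need >= 3 non-excluded subjects")
    vals = np.array([s.li_mean for s in active])
    mu, sd = vals.mean(), vals.std(ddof=1)
    out = []
    for s in subjects:
        if not s.excluded and sd > 0 and abs(s.li_mean - mu) > sd_limit * sd:
            out.append(replace(s, excluded=True, exclusion_reason="outlier_5sd"))
        else:
            out.append(replace(s))
    return out


def split_half_reliability(
    subjects: Sequence[SubjectLaterality],
) -> tuple[float, float]:
    """Pearson correlation between odd- and even-trial LIs across
    non-excluded subjects, plus the Spearman–Brown full-length value
    2r/(1+r) — reported separately, never silently substituted."""
    active = [s for s in subjects if not s.excluded]
    odd = np.array([s.li_odd for s in active])
    even = np.array([s.li_even for s in active])
    ok = np.isfinite(odd) & np.isfinite(even)
    odd, even = odd[ok], even[ok]
    if len(odd) < 3:
        raise DegenerateDataError("need >= 3 subjects with both half-LIs")
    if odd.std() == 0 or even.std() == 0:
        raise DegenerateDataError("zero variance in a half: correlation undefined")
    r = float(np.corrcoef(odd, even)[0, 1])
    sb = 2 * r / (1 + r) if r > -1.0 + 1e-12 else float("nan")
    return r, sb
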