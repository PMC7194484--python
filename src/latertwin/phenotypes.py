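"""Handedness-instrument scoring.

Two demonstration-based hand-preference instruments are scored here:

* the 10-item Edinburgh Handedness Inventory variant for children (EHI):
  one point per exclusively right-handed action, half a point when both
  hands are used, zero for left-handed use — range 0..10;
* the Quantification of Hand Preference card-reaching task (QHP): 21 card
  trials, three at each of seven positions spanning the midline; two
  points for right-handed pickup, one for a between-hand transfer, zero
  for left-handed pickup — range 0..42.

Both scores are monotone in the number of right-handed responses and
invariant to the order of items, which the tests assert.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .exceptions import MalformedInputError

EHI_N_ITEMS = 10
QHP_N_POSITIONS = 7
QHP_TRIALS_PER_POSITION = 3
QHP_N_TRIALS = QHP_N_POSITIONS * QHP_TRIALS_PER_POSITION

_EHI_POINTS = {"right": 1.0, "either": 0.5, "left": 0.0}
_QHP_POINTS = {"right": 2.0, "transfer": 1.0, "left": 0.0}


def _score(
    responses: Sequence[str],
    points: dict[str, float],
    n_expected: int,
    scale_max: float,
    allow_missing: bool,
) -> tuple[float, bool]:
    if len(responses) != n_expected:
        raise MalformedInputError(
            f"expected {n_expected} responses, got {len(responses)}"
        )
    raw = 0.0
    n_answered = 0
    for r in responses:
        if r is None or (isinstance(r, float) and pd.isna(r)) or r == "":
            continue
        if r not in points:
            raise MalformedInputError(f"invalid response {r!r}")
        raw += points[r]
        n_answered += 1
    if n_answered == n_expected:
        return raw, False
    if n_answered == 0 or not allow_missing:
        raise MalformedInputError("no scoreable responses")
    # prorate to the full scale; flagged so the caller can track uncertainty
    return raw * n_expected / n_answered, True


def score_ehi(responses: Sequence[str], allow_missing: bool = True) -> float:
    """Score a 10-item EHI response set; right=1, either=0.5, left=0."""
    score, _ = score_ehi_flagged(responses, allow_missing=allow_missing)
    return score


def score_ehi_flagged(
    responses: Sequence[str], allow_missing: bool = True
) -> tuple[float, bool]:
    """Like :func:`score_ehi` but also returns a prorated-for-missing flag."""
    return _score(responses, _EHI_POINTS, EHI_N_ITEMS, 10.0, allow_missing)


def score_qhp(
    responses: Sequence[str],
    positions: Sequence[int] | None = None,
    allow_missing: bool = True,
) -> float:
    """Score 21 QHP card trials; right=2, transfer=1, left=0.

    If ``positions`` is given it must assign exactly three trials to each
    of the seven positions (1..7); the spatial layout is bookkeeping only
    and does not enter the score.
    """
    score, _ = score_qhp_flagged(responses, positions, allow_missing=allow_missing)
    return score


def score_qhp_flagged(
    responses: Sequence[str],
    positions: Sequence[int] | None = None,
    allow_missing: bool = True,
) -> tuple[float, bool]:
    if positions is not None:
        if len(positions) != QHP_N_TRIALS:
            raise MalformedInputError("positions must cover all 21 trials")
        counts = pd.Series(list(positions)).value_counts()
        if sorted(counts.index) != list(range(1, QHP_N_POSITIONS + 1)) or (
            counts != QHP_TRIALS_PER_POSITION
        ).any():
            raise MalformedInputError("each of 7 positions needs exactly 3 trials")
    return _score(responses, _QHP_POINTS, QHP_N_TRIALS, 42.0, allow_missing)


def read_item_table(path) -> pd.DataFrame:
    """Read a wide item-level CSV and emit per-subject phenotype scores.

    Expected columns: ``subject_id``, ``ehi_1`` .. ``ehi_10`` and
    ``qhp_1`` .. ``qhp_21``; either block may be absent.  Returns a frame
    with ``subject_id``, ``ehi``, ``qhp`` and the prorating flags.
    """
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise MalformedInputError("item table needs a subject_id column")
    out: dict[str, list] = {"subject_id": []}
    ehi_cols = [f"ehi_{i}" for i in range(1, EHI_N_ITEMS + 1)]
    qhp_cols = [f"qhp_{i}" for i in range(1, QHP_N_TRIALS + 1)]
    have_ehi = all(c in df.columns for c in ehi_cols)
    have_qhp = all(c in df.columns for c in qhp_cols)
    if have_ehi:
        out["ehi"] = []
        out["ehi_prorated"] = []
    if have_qhp:
        out["qhp"] = []
        out["qhp_prorated"] = []
    for _, row in df.iterrows():
        out["subject_id"].append(row["subject_id"])
        if have_ehi:
            s, f = score_ehi_flagged([row[c] for c in ehi_cols])
            out["ehi"].append(s)
            out["ehi_prorated"].append(f)
        if have_qhp:
            s, f = score_qhp_flagged([row[c] for c in qhp_cols])
            out["qhp"].append(s)
            out["qhp_prorated"].append(f)
    return pd.DataFrame(out)
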