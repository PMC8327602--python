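"""Descriptive choice-rate analyses.

Actions are classified on two axes derived from the trial's state: *lucrative*
(L) vs *detrimental* (D) — did the chosen shape match the currently lucrative
one — and *informative* (I) vs *non-informative* (N) — was the chosen shape on
the side that reveals the reward.  Trials are of type I (choice between L∧I
and D∧N, when s1 == s2) or type II (L∧N vs D∧I).  All rates divide action
counts by valid-choice counts, so the two rates of a trial type are
complementary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ChoiceDataset
from .task import INFORMATIVE_ACTIONS, SQUARE_ACTIONS, StateSequence

__all__ = [
    "ChoiceRateSummary",
    "ReversalLockedRates",
    "classify_actions",
    "summary_choice_rates",
    "trialwise_group_rates",
    "reversal_locked_rates",
    "paired_rate_test",
]

_PARTICIPANT_RATES = [
    "valid_rate",
    "valid_rate_type1",
    "valid_rate_type2",
    "rate_LI",
    "rate_DN",
    "rate_LN",
    "rate_DI",
    "rate_lucrative",
    "rate_informative",
]


@dataclass
class ChoiceRateSummary:
    """Nine summary choice rates per participant plus group mean and SEM."""

    per_participant: pd.DataFrame  # one row per participant
    group: pd.DataFrame  # rows: rate names; columns: mean, sem


@dataclass
class ReversalLockedRates:
    """Per post-reversal position: L∧I and L∧N group-rate means, SEMs, diff.

    Positions beyond the shortest block aggregate fewer blocks; the number of
    contributing blocks is reported alongside each mean.
    """

    table: pd.DataFrame  # position, mean/sem/n for LI and LN, diff


def _check_alignment(dataset: ChoiceDataset, sequence: StateSequence) -> None:
    t = dataset.trials
    if len(t) != len(sequence):
        raise ValueError("dataset length does not match the state sequence")
    if not np.array_equal(t["s2"].to_numpy(np.int64), sequence.s2) or not np.array_equal(
        t["run"].to_numpy(np.int64), sequence.run
    ):
        raise ValueError("dataset does not share the given state sequence")


def classify_actions(
    dataset: ChoiceDataset, sequence: StateSequence
) -> pd.DataFrame:
    """Per-trial boolean frame: valid, lucrative, informative, trial type."""
    _check_alignment(dataset, sequence)
    t = dataset.trials
    valid = t["valid"].to_numpy(np.int64).astype(bool)
    action = t["action"].to_numpy()
    act = np.where(valid, action, 0).astype(np.int64)
    chose_square = np.isin(act, list(SQUARE_ACTIONS))
    lucrative = valid & (chose_square == (sequence.s1 == 1))
    informative = valid & np.isin(act, list(INFORMATIVE_ACTIONS))
    return pd.DataFrame(
        {
            "valid": valid,
            "lucrative": lucrative,
            "informative": informative,
            "trial_type": sequence.trial_type(),
        }
    )


def _participant_rates(dataset: ChoiceDataset, sequence: StateSequence) -> dict:
    c = classify_actions(dataset, sequence)
    type1 = c["trial_type"].to_numpy() == 1
    valid = c["valid"].to_numpy()
    luc = c["lucrative"].to_numpy()
    inf = c["informative"].to_numpy()
    n, n1, n2 = len(c), type1.sum(), (~type1).sum()
    v, v1, v2 = valid.sum(), (valid & type1).sum(), (valid & ~type1).sum()

    def rate(num: int, den: int) -> float:
        return num / den if den else np.nan

    return {
        "participant_id": dataset.trials["participant_id"].iloc[0],
        "valid_rate": rate(v, n),
        "valid_rate_type1": rate(v1, n1),
        "valid_rate_type2": rate(v2, n2),
        "rate_LI": rate((luc & inf & type1).sum(), v1),
        "rate_DN": rate((valid & ~luc & ~inf & type1).sum(), v1),
        "rate_LN": rate((luc & ~inf & ~type1).sum(), v2),
        "rate_DI": rate((valid & ~luc & inf & ~type1).sum(), v2),
        "rate_lucrative": rate(luc.sum(), v),
        "rate_informative": rate(inf.sum(), v),
    }


def summary_choice_rates(
    datasets: list[ChoiceDataset], sequence: StateSequence
) -> ChoiceRateSummary:
    """Summary rates per participant and their group mean and SEM."""
    if not datasets:
        raise ValueError("need at least one dataset")
    per = pd.DataFrame([_participant_rates(d, sequence) for d in datasets]).set_index(
        "participant_id"
    )
    n = len(per)
    group = pd.DataFrame(
        {
            "mean": per[_PARTICIPANT_RATES].mean(),
            "sem": per[_PARTICIPANT_RATES].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
        }
    )
    return ChoiceRateSummary(per_participant=per, group=group)


def trialwise_group_rates(
    datasets: list[ChoiceDataset], sequence: StateSequence
) -> pd.DataFrame:
    """Per-trial group action choice rates.

    Each trial carries one complementary rate pair (L∧I/D∧N on type I, and
    L∧N/D∧I on type II), computed over the participants with a valid choice
    on that trial; trials nobody answered validly yield missing rates.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    frames = [classify_actions(d, sequence) for d in datasets]
    valid = np.stack([f["valid"].to_numpy() for f in frames])
    luc = np.stack([f["lucrative"].to_numpy() for f in frames])
    inf = np.stack([f["informative"].to_numpy() for f in frames])
    n_valid = valid.sum(axis=0)
    ttype = sequence.trial_type()
    with np.errstate(invalid="ignore", divide="ignore"):
        luc_rate = np.where(n_valid > 0, luc.sum(axis=0) / n_valid, np.nan)
    out = pd.DataFrame(
        {
            "global_trial": np.arange(1, len(sequence) + 1),
            "run": sequence.run,
            "trial_type": ttype,
            "n_valid": n_valid,
            # lucrative-action rate of the trial's pair: L∧I on type I, L∧N on type II
            "rate_lucrative_pair": luc_rate,
            "rate_detrimental_pair": np.where(n_valid > 0, 1.0 - luc_rate, np.nan),
        }
    )
    # sanity: on type-I trials every valid lucrative choice is informative
    check = (luc & inf).sum(axis=0)
    mismatch = (ttype == 1) & (check != luc.sum(axis=0))
    if mismatch.any():
        raise AssertionError("lucrative type-I choices must be informative")
    return out


def reversal_positions(sequence: StateSequence) -> tuple[np.ndarray, np.ndarray]:
    """(position since block start, block id) per trial; run starts open a block."""
    pos = np.empty(len(sequence), dtype=np.int64)
    block = np.empty(len(sequence), dtype=np.int64)
    block_id = -1
    for i in range(len(sequence)):
        new_run = i == 0 or sequence.run[i] != sequence.run[i - 1]
        if new_run or sequence.s1[i] != sequence.s1[i - 1]:
            block_id += 1
            p = 0
        p += 1
        pos[i] = p
        block[i] = block_id
    return pos, block


def reversal_locked_rates(
    trialwise: pd.DataFrame, sequence: StateSequence
) -> ReversalLockedRates:
    """Average the trialwise L∧I and L∧N rates by post-reversal position.

    For every position since the last reversal (run starts count as block
    starts), the group rates of contributing type-I trials (L∧I) and type-II
    trials (L∧N) are averaged over blocks, with the SEM taken over blocks.
    Trials with missing rates are excluded.
    """
    pos, _ = reversal_positions(sequence)
    df = trialwise.assign(position=pos)
    df = df[np.isfinite(df["rate_lucrative_pair"])]
    rows = []
    for position, chunk in df.groupby("position"):
        li = chunk.loc[chunk["trial_type"] == 1, "rate_lucrative_pair"].to_numpy()
        ln = chunk.loc[chunk["trial_type"] == 2, "rate_lucrative_pair"].to_numpy()

        def msem(x: np.ndarray) -> tuple[float, float]:
            if len(x) == 0:
                return np.nan, np.nan
            sem = x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0
            return float(x.mean()), float(sem)

        m_li, s_li = msem(li)
        m_ln, s_ln = msem(ln)
        rows.append(
            {
                "position": position,
                "mean_LI": m_li,
                "sem_LI": s_li,
                "n_LI": len(li),
                "mean_LN": m_ln,
                "sem_LN": s_ln,
                "n_LN": len(ln),
                "diff": m_li - m_ln,
            }
        )
    return ReversalLockedRates(table=pd.DataFrame(rows))


def paired_rate_test(summary: ChoiceRateSummary) -> tuple[float, float]:
    """Two-sided paired t-test of the per-participant L∧I vs L∧N rates.

    Degenerate inputs follow an explicit contract: identical rate vectors
    give ``t = 0`` (with a warning); a constant nonzero difference gives a
    signed infinite t (with a warning).  Returns ``(t, p)`` with ``n - 1``
    degrees of freedom.
    """
    per = summary.per_participant
    x = per["rate_LI"].to_numpy(float)
    y = per["rate_LN"].to_numpy(float)
    if len(x) < 2:
        raise ValueError("need at least two participants for a paired test")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            warnings.warn("zero differences with zero variance; reporting t = 0")
            return 0.0, 1.0
        warnings.warn("constant nonzero difference; reporting infinite t")
        return float(np.sign(d.mean()) * np.inf), 0.0
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)
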