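"""Task-performance measures for PRL behavior.

Accuracy (proportion of choices of the currently correct stimulus,
overall and per phase), perseverative errors (reversal-phase choices of
the pre-reversal correct stimulus occurring in runs of two or more,
as a proportion of reversal trials), win-stay / lose-shift (repeating
a choice after reward / switching after punishment, as proportions of
eligible trials), and a per-phase learning criterion (one-sided exact
binomial test of phase accuracy against chance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .task import SubjectData

__all__ = [
    "BehaviorSummary",
    "accuracy_by_phase",
    "perseverative_errors",
    "win_stay",
    "lose_shift",
    "learning_criterion",
    "summarize_subject",
    "metrics_table",
    "group_summary",
]


@dataclass(frozen=True)
class BehaviorSummary:
    """Per-subject behavioral measures; NaN marks undefined proportions."""

    subject_id: str
    diagnosis: str
    age_group: str
    accuracy_overall: float
    accuracy_acquisition: float
    accuracy_reversal: float
    perseverative_errors: float
    win_stay: float
    lose_shift: float
    learning_pass_acquisition: bool
    learning_pass_reversal: bool


def accuracy_by_phase(data: SubjectData) -> tuple[float, float, float]:
    """(overall, acquisition, reversal) proportions of correct choices."""
    correct = data.correct
    acq = data.phase == "acquisition"
    return (
        float(correct.mean()),
        float(correct[acq].mean()),
        float(correct[~acq].mean()),
    )


def perseverative_errors(data: SubjectData, require_negative_feedback: bool = False) -> float:
    """Proportion of reversal-phase trials spent in perseverative runs.

    An error trial is a reversal-phase choice of the pre-reversal
    correct stimulus; trials belonging to runs of >= 2 consecutive such
    errors are counted and divided by the number of reversal trials.
    By default error trials count irrespective of the feedback each one
    drew (a misleading reward on an error trial does not break the
    run); ``require_negative_feedback=True`` restricts runs to error
    trials that received punishment.
    """
    rev = data.phase == "reversal"
    if not rev.any():
        raise ValueError("no reversal-phase trials")
    old_correct = data.correct_stim[~rev][0] if (~rev).any() else 1 - data.correct_stim[rev][0]
    err = data.choices[rev] == old_correct
    if require_negative_feedback:
        err = err & (data.outcomes[rev] < 0)
    count = 0
    run = 0
    for e in err:
        if e:
            run += 1
        else:
            if run >= 2:
                count += run
            run = 0
    if run >= 2:
        count += run
    return count / err.size


def _stay(choices: np.ndarray) -> np.ndarray:
    """stay[t] == True iff choice at t+1 repeats choice at t."""
    return choices[1:] == choices[:-1]


def win_stay(data: SubjectData) -> float:
    """P(repeat choice | previous trial rewarded); NaN if no eligible trial."""
    won = data.outcomes[:-1] > 0
    if not won.any():
        return math.nan
    return float(_stay(data.choices)[won].mean())


def lose_shift(data: SubjectData) -> float:
    """P(switch choice | previous trial punished); NaN if no eligible trial."""
    lost = data.outcomes[:-1] < 0
    if not lost.any():
        return math.nan
    return float((~_stay(data.choices))[lost].mean())


def learning_criterion(data: SubjectData, level: float = 0.05) -> tuple[bool, bool]:
    """Per-phase pass/fail: one-sided exact binomial test vs chance.

    A phase passes when the number of correct choices rejects
    p = 0.5 in favour of p > 0.5 at the given level.
    """
    correct = data.correct
    acq = data.phase == "acquisition"
    out = []
    for mask in (acq, ~acq):
        k, n = int(correct[mask].sum()), int(mask.sum())
        p = stats.binomtest(k, n, p=0.5, alternative="greater").pvalue
        out.append(p < level)
    return tuple(out)


def summarize_subject(data: SubjectData) -> BehaviorSummary:
    overall, acq, rev = accuracy_by_phase(data)
    pass_acq, pass_rev = learning_criterion(data)
    return BehaviorSummary(
        subject_id=data.subject_id,
        diagnosis=data.diagnosis,
        age_group=data.age_group,
        accuracy_overall=overall,
        accuracy_acquisition=acq,
        accuracy_reversal=rev,
        perseverative_errors=perseverative_errors(data),
        win_stay=win_stay(data),
        lose_shift=lose_shift(data),
        learning_pass_acquisition=pass_acq,
        learning_pass_reversal=pass_rev,
    )


def metrics_table(cohort: list[SubjectData]) -> pd.DataFrame:
    """One row of behavioral measures per subject."""
    return pd.DataFrame([asdict(summarize_subject(s)) for s in cohort])


def group_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Group means (SDs) of the behavioral measures, one row per group."""
    value_cols = [
        "accuracy_overall",
        "accuracy_acquisition",
        "accuracy_reversal",
        "perseverative_errors",
        "win_stay",
        "lose_shift",
    ]
    g = metrics.groupby(["age_group", "diagnosis"], sort=False)
    out = g[value_cols].agg(["mean", "std"])
    out.columns = [f"{c}_{s}" for c, s in out.columns]
    out["n"] = g.size()
    return out.reset_index()
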