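"""Probabilistic reversal learning (PRL) task structure and feedback semantics.

The task presents two stimuli, A and B, over a fixed number of trials.
Whichever stimulus the participant chooses first is coded as the
"correct" (usually rewarded) stimulus for the acquisition phase; at the
reversal the other stimulus becomes correct.  Feedback follows a fixed
pseudorandom schedule: on each trial the currently correct stimulus is
assigned an outcome of +1 (reward) or -1 (punishment), with rewards
delivered at ``p_reward`` exactly per phase (80:20 at defaults).  The
two stimuli are anti-correlated: choosing the incorrect stimulus yields
the negated scheduled outcome, so a "misleading" punishment for the
correct choice is a misleading reward for the incorrect one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "STIMULI",
    "TaskSchedule",
    "SubjectData",
    "build_schedule",
    "deliver_outcome",
    "assign_correct_stimulus",
]

STIMULI = ("A", "B")

#: Maximum run of consecutive scheduled punishments within a phase.  A
#: longer run would look like a brief contingency reversal to the
#: participant, which the fixed sequence is designed to avoid.
MAX_PUNISHMENT_RUN = 2


@dataclass(frozen=True)
class TaskSchedule:
    """Fixed feedback plan for one PRL session.

    Attributes
    ----------
    n_trials : int
        Total number of trials (default task: 80).
    reversal_trial : int
        1-based index of the first reversal-phase trial (default: 41).
    p_reward : float
        Probability that choosing the currently correct stimulus is
        rewarded; realised exactly per phase, not just in expectation.
    scheduled_outcome : numpy.ndarray
        Per-trial outcome (+1/-1) delivered if the currently correct
        stimulus is chosen; length ``n_trials``.
    seed : int
        Seed used to place punishments within each phase.
    """

    n_trials: int
    reversal_trial: int
    p_reward: float
    scheduled_outcome: np.ndarray = field(repr=False)
    seed: int

    def __post_init__(self) -> None:
        out = np.asarray(self.scheduled_outcome, dtype=np.int8)
        if out.shape != (self.n_trials,):
            raise ValueError("scheduled_outcome length must equal n_trials")
        if not np.isin(out, (-1, 1)).all():
            raise ValueError("scheduled outcomes must be +1 or -1")
        if not (1 < self.reversal_trial <= self.n_trials):
            raise ValueError("reversal_trial must lie in (1, n_trials]")
        object.__setattr__(self, "scheduled_outcome", out)

    @property
    def phase(self) -> np.ndarray:
        """'acquisition'/'reversal' label per trial."""
        trials = np.arange(1, self.n_trials + 1)
        return np.where(trials < self.reversal_trial, "acquisition", "reversal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "phase": self.phase,
                "scheduled_outcome": self.scheduled_outcome,
            }
        )


def _place_punishments(phase_len: int, n_pun: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean punishment mask with no run longer than MAX_PUNISHMENT_RUN."""
    if n_pun > phase_len:
        raise ValueError("more punishments than trials in phase")
    for _ in range(10_000):
        mask = np.zeros(phase_len, dtype=bool)
        mask[rng.choice(phase_len, size=n_pun, replace=False)] = True
        if n_pun == 0:
            return mask
        edges = np.diff(np.r_[0, mask.view(np.int8), 0])
        run_lengths = np.flatnonzero(edges == -1) - np.flatnonzero(edges == 1)
        if run_lengths.max() <= MAX_PUNISHMENT_RUN:
            return mask
    raise RuntimeError("could not place punishments under run-length cap")


def build_schedule(
    n_trials: int = 80,
    reversal_trial: int = 41,
    p_reward: float = 0.8,
    seed: int = 0,
) -> TaskSchedule:
    """Build the fixed pseudorandom feedback schedule.

    Each phase receives exactly ``round(p_reward * phase_len)`` rewards;
    the punishments are placed uniformly at random within the phase,
    subject to the run-length cap.  The same seed always yields an
    identical schedule.

    Raises
    ------
    ValueError
        If ``p_reward * phase_len`` is not a whole number for either
        phase (the exact-count contract would be unsatisfiable).
    """
    if not 1 < reversal_trial <= n_trials:
        raise ValueError("reversal_trial must lie in (1, n_trials]")
    if not 0.0 <= p_reward <= 1.0:
        raise ValueError("p_reward must be a probability")
    rng = np.random.default_rng(seed)
    bounds = [(0, reversal_trial - 1), (reversal_trial - 1, n_trials)]
    for lo, hi in bounds:
        n_reward = p_reward * (hi - lo)
        if abs(n_reward - round(n_reward)) > 1e-9:
            raise ValueError(
                f"p_reward={p_reward} does not give a whole number of rewards "
                f"over a {hi - lo}-trial phase; choose a compatible split"
            )
    for _ in range(10_000):
        out = np.ones(n_trials, dtype=np.int8)
        for lo, hi in bounds:
            phase_len = hi - lo
            mask = _place_punishments(phase_len, phase_len - round(p_reward * phase_len), rng)
            out[lo:hi][mask] = -1
        # the cap must also hold across the phase boundary
        edges = np.diff(np.r_[0, (out == -1).view(np.int8), 0])
        lengths = np.flatnonzero(edges == -1) - np.flatnonzero(edges == 1)
        if lengths.max(initial=0) <= MAX_PUNISHMENT_RUN:
            break
    else:
        raise RuntimeError("could not place punishments under run-length cap")
    return TaskSchedule(
        n_trials=n_trials,
        reversal_trial=reversal_trial,
        p_reward=p_reward,
        scheduled_outcome=out,
        seed=seed,
    )


def assign_correct_stimulus(first_choice: str) -> tuple[str, str]:
    """Map the first choice to (acquisition, reversal) correct stimuli.

    The participant's first stimulus choice is coded correct for the
    acquisition phase; after the reversal the other stimulus is correct.
    """
    if first_choice not in STIMULI:
        raise ValueError(f"unknown stimulus {first_choice!r}")
    other = "B" if first_choice == "A" else "A"
    return first_choice, other


def deliver_outcome(
    schedule: TaskSchedule, trial: int, choice: str, correct_stim: str
) -> int:
    """Outcome (+1/-1) for a choice on a 1-based trial.

    The scheduled outcome applies to the currently correct stimulus;
    the incorrect stimulus receives its negation (anti-correlated
    feedback).
    """
    if choice not in STIMULI or correct_stim not in STIMULI:
        raise ValueError("stimulus labels must be 'A' or 'B'")
    if not 1 <= trial <= schedule.n_trials:
        raise ValueError(f"trial {trial} outside schedule")
    scheduled = int(schedule.scheduled_outcome[trial - 1])
    return scheduled if choice == correct_stim else -scheduled


@dataclass
class SubjectData:
    """One subject's choice-outcome sequence with group labels.

    Choices are stored as an integer array (0 = stimulus A, 1 = B) and
    outcomes as +1/-1, both of length ``n_trials``.  ``correct_stim``
    holds the currently correct stimulus index per trial, flipping
    exactly once at ``reversal_trial``.
    """

    subject_id: str
    diagnosis: str
    age_group: str
    choices: np.ndarray
    outcomes: np.ndarray
    correct_stim: np.ndarray
    reversal_trial: int

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=np.int8)
        self.outcomes = np.asarray(self.outcomes, dtype=np.int8)
        self.correct_stim = np.asarray(self.correct_stim, dtype=np.int8)
        n = self.n_trials
        if not (self.outcomes.shape == self.correct_stim.shape == (n,)):
            raise ValueError("choices, outcomes, correct_stim must share length")
        if not np.isin(self.outcomes, (-1, 1)).all():
            raise ValueError("outcomes must be +1 or -1")
        if not np.isin(self.choices, (0, 1)).all():
            raise ValueError("choices must be 0 (A) or 1 (B)")
        flips = np.flatnonzero(np.diff(self.correct_stim)) + 2  # 1-based trial of flip
        if flips.size != 1 or flips[0] != self.reversal_trial:
            raise ValueError("correct_stim must flip exactly once, at reversal_trial")

    @property
    def n_trials(self) -> int:
        return len(self.choices)

    @property
    def phase(self) -> np.ndarray:
        trials = np.arange(1, self.n_trials + 1)
        return np.where(trials < self.reversal_trial, "acquisition", "reversal")

    @property
    def correct(self) -> np.ndarray:
        """Boolean per-trial correctness (choice == currently correct)."""
        return self.choices == self.correct_stim

    def to_frame(self) -> pd.DataFrame:
        labels = np.array(STIMULI)
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "diagnosis": self.diagnosis,
                "age_group": self.age_group,
                "trial": np.arange(1, self.n_trials + 1),
                "phase": self.phase,
                "choice": labels[self.choices],
                "outcome": self.outcomes,
                "correct_stim": labels[self.correct_stim],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SubjectData":
        """Rebuild one subject from trial-level rows (one subject only)."""
        df = df.sort_values("trial")
        subject_ids = df["subject_id"].unique()
        if len(subject_ids) != 1:
            raise ValueError("from_frame expects rows for exactly one subject")
        trials = df["trial"].to_numpy()
        if not np.array_equal(trials, np.arange(1, len(trials) + 1)):
            raise ValueError(f"subject {subject_ids[0]}: trials not contiguous from 1")
        choice_idx = np.searchsorted(STIMULI, df["choice"].to_numpy())
        correct_idx = np.searchsorted(STIMULI, df["correct_stim"].to_numpy())
        flips = np.flatnonzero(np.diff(correct_idx))
        if flips.size != 1:
            raise ValueError(f"subject {subject_ids[0]}: expected exactly one reversal")
        return cls(
            subject_id=str(subject_ids[0]),
            diagnosis=str(df["diagnosis"].iloc[0]),
            age_group=str(df["age_group"].iloc[0]),
            choices=choice_idx,
            outcomes=df["outcome"].to_numpy(),
            correct_stim=correct_idx,
            reversal_trial=int(flips[0] + 2),
        )


def cohort_to_frame(cohort: list[SubjectData]) -> pd.DataFrame:
    """Concatenate subjects into one trial-level table."""
    return pd.concat([s.to_frame() for s in cohort], ignore_index=True)


def cohort_from_frame(df: pd.DataFrame) -> list[SubjectData]:
    """Split a trial-level table into subjects, validating each."""
    return [
        SubjectData.from_frame(g) for _, g in df.groupby("subject_id", sort=False)
    ]
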