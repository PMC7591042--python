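"""Synthetic cohorts emulating the six-group PRL study design.

The study fit separate models to six groups — diagnosis (ASD, TD) x
developmental stage (children, adolescents, adults) — and reported, for
each age group's winning model, group parameter means and SDs.  No raw
data were deposited, so this module generates synthetic stand-ins:
agents simulated from a chosen model with individual parameters drawn
from truncated normals at those group-level values.  Ground-truth
parameters are always stored alongside the simulated behavior, which is
what makes parameter- and model-recovery tests possible.

``DEFAULT_GROUP_SPECS`` encodes the published group structure: children
best fit by the counterfactual-update model, adolescents by the
reward-punishment model, adults by EWA-DL, with the published means,
SDs, and group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import FOCAL_PARAM, MODEL_IDS, MODEL_PARAMS, PARAM_BOUNDS, ParamVector
from .task import STIMULI, SubjectData, TaskSchedule, build_schedule

__all__ = [
    "GroupSpec",
    "DEFAULT_GROUP_SPECS",
    "simulate_agent",
    "simulate_batch",
    "generate_cohort",
    "recovery_set",
    "ground_truth_frame",
]


@dataclass(frozen=True)
class GroupSpec:
    """Generative recipe for one diagnosis x age group."""

    diagnosis: str
    age_group: str
    model_id: str
    param_means: dict[str, float]
    param_sds: dict[str, float]
    n_subjects: int

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model_id!r}")
        expected = set(MODEL_PARAMS[self.model_id])
        if set(self.param_means) != expected or set(self.param_sds) != expected:
            raise ValueError(f"{self.model_id} needs means and SDs for {sorted(expected)}")
        for name, m in self.param_means.items():
            lo, hi = PARAM_BOUNDS[name]
            if not lo <= m <= hi:
                raise ValueError(f"mean {name}={m} outside [{lo}, {hi}]")
            if self.param_sds[name] < 0:
                raise ValueError(f"SD of {name} must be >= 0")

    @property
    def label(self) -> str:
        return f"{self.diagnosis}-{self.age_group}"


#: Published group-level parameter means (SDs) for each age group's
#: winning model, with the study's group sizes.
DEFAULT_GROUP_SPECS: tuple[GroupSpec, ...] = (
    GroupSpec(
        "ASD", "children", "CU",
        {"eta": 0.258, "beta": 0.979, "alpha": -0.014},
        {"eta": 0.126, "beta": 0.783, "alpha": 0.319},
        81,
    ),
    GroupSpec(
        "TD", "children", "CU",
        {"eta": 0.193, "beta": 1.202, "alpha": -0.042},
        {"eta": 0.087, "beta": 0.892, "alpha": 0.153},
        64,
    ),
    GroupSpec(
        "ASD", "adolescents", "RP",
        {"eta_rew": 0.368, "eta_pun": 0.336, "beta": 1.494, "alpha": -0.032},
        {"eta_rew": 0.169, "eta_pun": 0.098, "beta": 0.897, "alpha": 0.255},
        114,
    ),
    GroupSpec(
        "TD", "adolescents", "RP",
        {"eta_rew": 0.443, "eta_pun": 0.311, "beta": 2.535, "alpha": -0.031},
        {"eta_rew": 0.223, "eta_pun": 0.116, "beta": 1.108, "alpha": 0.161},
        90,
    ),
    GroupSpec(
        "ASD", "adults", "EWA_DL",
        {"phi": 0.521, "rho": 0.379, "beta": 1.231, "alpha": -0.052},
        {"phi": 0.185, "rho": 0.268, "beta": 0.742, "alpha": 0.308},
        126,
    ),
    GroupSpec(
        "TD", "adults", "EWA_DL",
        {"phi": 0.587, "rho": 0.308, "beta": 1.290, "alpha": 0.040},
        {"phi": 0.101, "rho": 0.200, "beta": 0.763, "alpha": 0.344},
        97,
    ),
)


def _draw_truncnorm(
    mean: float, sd: float, lo: float, hi: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Truncated-normal draws on [lo, hi]; degenerate SD=0 returns the mean."""
    if sd == 0.0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    mass = stats.norm.cdf(b) - stats.norm.cdf(a)
    if mass < 1e-10:
        raise ValueError(
            f"truncated normal (mean={mean}, sd={sd}) has ~no mass inside [{lo}, {hi}]"
        )
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_batch(
    model_id: str,
    params: dict[str, np.ndarray],
    schedule: TaskSchedule,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate many agents in lockstep on one schedule.

    ``params`` values are arrays broadcastable to a common shape whose
    last axis indexes agents (any lead axes, e.g. a parameter grid, are
    allowed).  Each agent's first choice is sampled from the softmax at
    the initial state (p(A) = 1/(1+exp(beta*alpha))) and defines its
    acquisition-correct stimulus; feedback is anti-correlated around
    the scheduled outcome; the model state evolves trial by trial.

    Returns ``(choices, outcomes, correct)`` arrays of shape
    ``shape + (n_trials,)`` with choices coded 0 = A / 1 = B and
    ``correct`` boolean (choice equalled the currently correct
    stimulus).
    """
    from scipy.special import expit

    p = {k: np.asarray(v, dtype=float) for k, v in params.items()}
    shape = np.broadcast_shapes(*(a.shape for a in p.values()))
    if shape == ():
        shape = (1,)
    beta, alpha = p["beta"], p["alpha"]
    T = schedule.n_trials
    rev = schedule.reversal_trial
    sched = schedule.scheduled_outcome

    va = np.zeros(shape)
    vb = np.zeros(shape)
    if model_id == "EWA_DL":
        na = np.ones(shape)
        nb = np.ones(shape)
    choices = np.empty(shape + (T,), dtype=np.int8)
    outcomes = np.empty(shape + (T,), dtype=np.int8)
    correct = np.empty(shape + (T,), dtype=bool)

    for t in range(T):
        p_a = expit(beta * (va - vb - alpha))
        chose_a = rng.random(shape) < p_a
        if t == 0:
            first_a = chose_a.copy()
        corr_a = first_a if (t + 1) < rev else ~first_a
        hit = chose_a == corr_a
        o = np.where(hit, sched[t], -sched[t]).astype(float)
        choices[..., t] = np.where(chose_a, 0, 1)
        outcomes[..., t] = o
        correct[..., t] = hit
        if model_id in ("RW", "CU"):
            eta = p["eta"]
            if model_id == "CU":
                va = np.where(chose_a, va + eta * (o - va), va + eta * (-o - va))
                vb = np.where(chose_a, vb + eta * (-o - vb), vb + eta * (o - vb))
            else:
                va = np.where(chose_a, va + eta * (o - va), va)
                vb = np.where(chose_a, vb, vb + eta * (o - vb))
        elif model_id == "RP":
            eta = np.where(o > 0, p["eta_rew"], p["eta_pun"])
            va = np.where(chose_a, va + eta * (o - va), va)
            vb = np.where(chose_a, vb, vb + eta * (o - vb))
        elif model_id == "EWA_DL":
            phi, rho = p["phi"], p["rho"]
            na_new = np.where(chose_a, na * rho + 1.0, na)
            nb_new = np.where(chose_a, nb, nb * rho + 1.0)
            va = np.where(chose_a, (va * phi * na + o) / na_new, va)
            vb = np.where(chose_a, vb, (vb * phi * nb + o) / nb_new)
            na, nb = na_new, nb_new
        else:
            raise ValueError(f"unknown model {model_id!r}")

    return choices, outcomes, correct


def _subject_from_sim(
    subject_id: str,
    diagnosis: str,
    age_group: str,
    choices: np.ndarray,
    outcomes: np.ndarray,
    reversal_trial: int,
) -> SubjectData:
    first = int(choices[0])
    T = len(choices)
    correct_stim = np.where(np.arange(1, T + 1) < reversal_trial, first, 1 - first)
    return SubjectData(
        subject_id=subject_id,
        diagnosis=diagnosis,
        age_group=age_group,
        choices=choices,
        outcomes=outcomes,
        correct_stim=correct_stim,
        reversal_trial=reversal_trial,
    )


def simulate_agent(
    model_id: str,
    params: ParamVector | dict,
    schedule: TaskSchedule,
    seed: int,
    subject_id: str = "sim",
    diagnosis: str = "NA",
    age_group: str = "NA",
) -> SubjectData:
    """Simulate one agent; fully reproducible from the seed."""
    if isinstance(params, ParamVector):
        if params.model_id != model_id:
            raise ValueError("params do not match model_id")
        params = params.params
    rng = np.random.default_rng(seed)
    arrays = {k: np.asarray([v], dtype=float) for k, v in params.items()}
    choices, outcomes, _ = simulate_batch(model_id, arrays, schedule, rng)
    return _subject_from_sim(
        subject_id, diagnosis, age_group, choices[0], outcomes[0], schedule.reversal_trial
    )


def generate_cohort(
    specs: list[GroupSpec] | tuple[GroupSpec, ...] = DEFAULT_GROUP_SPECS,
    schedule: TaskSchedule | None = None,
    seed: int = 0,
) -> tuple[list[SubjectData], pd.DataFrame]:
    """Draw per-subject parameters per group and simulate each subject.

    Two independent RNG streams derive from the master seed: one for
    the parameter draws, one for task feedback/choice noise, so tests
    can vary the noise sources independently.

    Returns the cohort and a ground-truth table (subject_id, group
    labels, model_id, one column per parameter).
    """
    if not specs:
        raise ValueError("specs must be nonempty")
    if schedule is None:
        schedule = build_schedule(seed=seed)
    param_rng, task_rng = [
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)
    ]
    cohort: list[SubjectData] = []
    truth_rows: list[dict] = []
    for spec in specs:
        n = spec.n_subjects
        if n == 0:
            continue
        drawn = {
            name: _draw_truncnorm(
                spec.param_means[name],
                spec.param_sds[name],
                *PARAM_BOUNDS[name],
                n,
                param_rng,
            )
            for name in MODEL_PARAMS[spec.model_id]
        }
        choices, outcomes, _ = simulate_batch(spec.model_id, drawn, schedule, task_rng)
        for i in range(n):
            sid = f"{spec.label}-{i + 1:03d}"
            cohort.append(
                _subject_from_sim(
                    sid, spec.diagnosis, spec.age_group,
                    choices[i], outcomes[i], schedule.reversal_trial,
                )
            )
            truth_rows.append(
                {
                    "subject_id": sid,
                    "diagnosis": spec.diagnosis,
                    "age_group": spec.age_group,
                    "model_id": spec.model_id,
                    **{k: drawn[k][i] for k in drawn},
                }
            )
    return cohort, pd.DataFrame(truth_rows)


def recovery_set(
    model_id: str,
    n_subjects: int = 40,
    schedule: TaskSchedule | None = None,
    seed: int = 0,
) -> tuple[list[SubjectData], pd.DataFrame]:
    """Synthetic participants for model recovery.

    Parameters are drawn uniformly over each parameter's support (the
    generating distribution of the recovery participants was not
    published; uniform-over-support is this package's stated choice).
    Returns the cohort plus the ground-truth table carrying the
    generating model label.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}")
    if schedule is None:
        schedule = build_schedule(seed=seed)
    param_rng, task_rng = [
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)
    ]
    drawn = {}
    for name in MODEL_PARAMS[model_id]:
        lo, hi = PARAM_BOUNDS[name]
        drawn[name] = param_rng.uniform(lo, hi, size=n_subjects)
    choices, outcomes, _ = simulate_batch(model_id, drawn, schedule, task_rng)
    cohort = []
    rows = []
    for i in range(n_subjects):
        sid = f"{model_id}-rec-{i + 1:03d}"
        cohort.append(
            _subject_from_sim(
                sid, "SIM", model_id, choices[i], outcomes[i], schedule.reversal_trial
            )
        )
        rows.append(
            {"subject_id": sid, "model_id": model_id, **{k: drawn[k][i] for k in drawn}}
        )
    return cohort, pd.DataFrame(rows)


def ground_truth_frame(truth: pd.DataFrame) -> pd.DataFrame:
    """Sidecar table in its serialised column order."""
    lead = [c for c in ("subject_id", "diagnosis", "age_group", "model_id") if c in truth]
    rest = [c for c in truth.columns if c not in lead]
    return truth[lead + rest]
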