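"""Absolute model fit and optimal-learning-parameter simulations.

One-step-ahead prediction checks whether a fitted model reproduces a
subject's behavior: for each posterior draw the model state is evolved
along the subject's *recorded* choices and outcomes, and before each
trial's record is revealed a choice is sampled from the softmax; the
fraction of sampled choices matching the recorded ones is the
predictive accuracy, tested against chance (50%) with an exact
binomial test.

The optimality grids ask which learning parameters a given model
*should* use on this task: agents are simulated across a grid of the
learning parameter(s) with beta and alpha fixed, and mean accuracy
against the currently correct stimulus is the score.  The argmax is
the optimal learning parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import simulate_batch
from .hba import PosteriorDraws
from .models import MODEL_PARAMS, batch_loglik
from .task import SubjectData, TaskSchedule, build_schedule

__all__ = [
    "PredictionResult",
    "OptimalGridResult",
    "one_step_ahead",
    "cohort_one_step_ahead",
    "optimal_learning_params",
    "DEFAULT_OPTIMALITY_BETA",
]

#: Beta used when simulating each model's optimality grid: the fitted
#: group-level value-sensitivity of the age group the model won
#: (children/CU ~1.2, adolescents/RP ~2.5, adults/EWA-DL ~1.3).
DEFAULT_OPTIMALITY_BETA: dict[str, float] = {
    "RW": 1.2,
    "CU": 1.2,
    "RP": 2.5,
    "EWA_DL": 1.3,
}

#: Learning-parameter grid axes per model (1-D for RW/CU, 2-D otherwise).
GRID_AXES: dict[str, tuple[str, ...]] = {
    "RW": ("eta",),
    "CU": ("eta",),
    "RP": ("eta_rew", "eta_pun"),
    "EWA_DL": ("phi", "rho"),
}


@dataclass(frozen=True)
class PredictionResult:
    """One-step-ahead outcome for a single subject."""

    subject_id: str
    n_draws: int
    n_trials: int
    trial_match_freq: np.ndarray  # per-trial fraction of draws matching
    accuracy: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must be a proportion")


@dataclass(frozen=True)
class OptimalGridResult:
    """Accuracy surface over a learning-parameter grid."""

    model_id: str
    axes: tuple[str, ...]
    grid: tuple[np.ndarray, ...]
    accuracy: np.ndarray
    optimum: dict[str, float]
    n_sims: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        mesh = np.meshgrid(*self.grid, indexing="ij")
        cells = self.accuracy.size
        se = np.sqrt(self.accuracy * (1 - self.accuracy) / self.n_sims)
        df = pd.DataFrame({ax: m.ravel() for ax, m in zip(self.axes, mesh)})
        df["accuracy"] = self.accuracy.ravel()
        df["se"] = se.ravel()
        return df


def one_step_ahead(
    draws: PosteriorDraws,
    data: SubjectData,
    n_iter: int | None = None,
    seed: int = 0,
) -> PredictionResult:
    """Posterior predictive accuracy for one subject.

    Each of ``n_iter`` posterior draws replays the subject's recorded
    history; the sampled pre-trial choices are compared with the
    recorded ones.  The accuracy denominator is n_iter * n_trials.
    """
    try:
        idx = draws.subject_ids.index(data.subject_id)
    except ValueError:
        raise ValueError(f"subject {data.subject_id!r} not in posterior draws") from None
    theta = draws.subject_draws()[:, idx, :]  # (n_draws, P)
    if n_iter is None:
        n_iter = theta.shape[0]
    if n_iter > theta.shape[0]:
        raise ValueError(f"n_iter={n_iter} exceeds available draws {theta.shape[0]}")
    theta = theta[:n_iter]
    params = {n: theta[:, j] for j, n in enumerate(draws.param_names)}

    # Evolve the state along the recorded history for every draw at
    # once, capturing the pre-update choice probability per trial.
    _, per_trial = batch_loglik(
        draws.model_id,
        {k: v[:, None] for k, v in params.items()},
        data.choices[None, :],
        data.outcomes[None, :],
        per_trial=True,
    )
    # per_trial holds log p(recorded choice); sample matches directly
    p_match = np.exp(per_trial[:, 0, :])  # (n_iter, T)
    rng = np.random.default_rng(seed)
    matches = rng.random(p_match.shape) < p_match
    accuracy = float(matches.mean())
    test = stats.binomtest(int(matches.sum()), matches.size, p=0.5, alternative="greater")
    return PredictionResult(
        subject_id=data.subject_id,
        n_draws=n_iter,
        n_trials=data.n_trials,
        trial_match_freq=matches.mean(axis=0),
        accuracy=accuracy,
        p_value=float(test.pvalue),
    )


def cohort_one_step_ahead(
    draws: PosteriorDraws,
    cohort_subset: list[SubjectData],
    n_iter: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject one-step-ahead summary for a fitted group."""
    rows = []
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(cohort_subset))
    for s, sd in zip(cohort_subset, seeds):
        r = one_step_ahead(draws, s, n_iter=n_iter, seed=int(sd))
        rows.append(
            {
                "subject_id": r.subject_id,
                "accuracy": r.accuracy,
                "p_value": r.p_value,
                "n_draws": r.n_draws,
            }
        )
    return pd.DataFrame(rows)


def optimal_learning_params(
    model_id: str,
    schedule: TaskSchedule | None = None,
    grid_spec: int | tuple[np.ndarray, ...] = 101,
    n_sims: int = 2000,
    beta: float | None = None,
    alpha: float = 0.0,
    seed: int = 0,
) -> OptimalGridResult:
    """Accuracy surface and argmax over the learning-parameter grid.

    ``grid_spec`` is either the number of points per axis on [0, 1]
    (101 by default; the RW/CU grid is 1-D, RP and EWA-DL grids are
    2-D) or an explicit tuple of axis arrays.  ``n_sims`` agents are
    simulated per grid point with beta and alpha fixed; accuracy is
    scored against the currently correct stimulus on every trial,
    including the reversal phase.  Grid ties break toward the smaller
    parameter value.
    """
    if model_id not in GRID_AXES:
        raise ValueError(f"unknown model {model_id!r}")
    axes = GRID_AXES[model_id]
    if schedule is None:
        schedule = build_schedule(seed=seed)
    if beta is None:
        beta = DEFAULT_OPTIMALITY_BETA[model_id]
    if isinstance(grid_spec, int):
        if grid_spec < 1:
            raise ValueError("empty grid")
        grid = tuple(np.linspace(0.0, 1.0, grid_spec) for _ in axes)
    else:
        grid = tuple(np.asarray(g, dtype=float) for g in grid_spec)
        if len(grid) != len(axes) or any(g.size == 0 for g in grid):
            raise ValueError(f"{model_id} needs {len(axes)} nonempty grid axes")
    mesh = np.meshgrid(*grid, indexing="ij")
    shape = mesh[0].shape
    n_cells = mesh[0].size
    flat = {ax: m.reshape(-1) for ax, m in zip(axes, mesh)}
    rng = np.random.default_rng(seed)
    # bound the simulated block at ~4e5 agents to keep memory flat
    cells_per_chunk = max(1, int(400_000 // max(n_sims, 1)))
    acc_flat = np.empty(n_cells)
    for lo in range(0, n_cells, cells_per_chunk):
        hi = min(lo + cells_per_chunk, n_cells)
        params = {
            ax: np.broadcast_to(flat[ax][lo:hi, None], (hi - lo, n_sims))
            for ax in axes
        }
        params["beta"] = np.asarray(beta, dtype=float)
        params["alpha"] = np.asarray(alpha, dtype=float)
        _, _, correct = simulate_batch(model_id, params, schedule, rng)
        acc_flat[lo:hi] = correct.mean(axis=(1, 2))
    accuracy = acc_flat.reshape(shape)
    # first occurrence of the max = smallest grid values (row-major order)
    flat_idx = int(np.argmax(accuracy))
    opt_idx = np.unravel_index(flat_idx, shape)
    optimum = {ax: float(grid[d][opt_idx[d]]) for d, ax in enumerate(axes)}
    return OptimalGridResult(
        model_id=model_id,
        axes=axes,
        grid=grid,
        accuracy=accuracy,
        optimum=optimum,
        n_sims=n_sims,
        seed=seed,
    )
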