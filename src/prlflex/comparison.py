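"""Model comparison: pseudo-BMA weights with Bayesian-bootstrap stabilization.

For each candidate model, the posterior log-likelihood matrix
(draws x subjects) is reduced to a per-subject expected log predictive
density (elpd) with a complexity penalty: the penalty is the gap
between the log of the posterior-mean likelihood and the posterior
mean of the log-likelihood — the "effective number of parameters" a
subject consumes.  A Bayesian bootstrap over subjects (Dirichlet(1)
weights) then turns elpd differences into a stabilized weight simplex:
each replicate softmax-normalizes the weighted elpd totals across
models, and replicates are averaged.  A PSIS-LOO elpd (via arviz) is
the configurable alternative estimator.

Model recovery refits synthetic cohorts of known provenance with every
candidate model and tabulates which model wins, as a confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .hba import MCMCConfig, fit_group, pointwise_loglik
from .models import MODEL_PARAMS
from .task import SubjectData, TaskSchedule, build_schedule

__all__ = ["ModelWeights", "elpd_pointwise", "model_weights", "recover_models"]

#: Models entered into the comparison by default (the three main models).
DEFAULT_MODEL_SET = ("CU", "RP", "EWA_DL")


@dataclass(frozen=True)
class ModelWeights:
    """Per-group weight simplex plus the elpd bookkeeping behind it."""

    group: str
    weights: dict[str, float]
    elpd: dict[str, float]
    penalty: dict[str, float]
    n_bootstrap: int

    def __post_init__(self) -> None:
        w = np.array(list(self.weights.values()))
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be a simplex")

    @property
    def winner(self) -> str:
        """Winning model; ties break toward fewer parameters."""
        return min(
            self.weights,
            key=lambda m: (-self.weights[m], len(MODEL_PARAMS[m])),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "model": list(self.weights),
                "weight": list(self.weights.values()),
                "elpd": [self.elpd[m] for m in self.weights],
                "penalty": [self.penalty[m] for m in self.weights],
            }
        )


def elpd_pointwise(loglik: np.ndarray, method: str = "mean") -> tuple[np.ndarray, np.ndarray]:
    """Per-subject elpd estimate and complexity penalty.

    ``loglik`` has shape (n_draws, n_subjects).  With ``method="mean"``
    the penalty p_i = lpd_i - mean_s ll_si is subtracted from the log
    posterior-mean likelihood lpd_i, so elpd_i equals the posterior
    mean log-likelihood.  ``method="loo"`` uses PSIS-LOO (arviz) with
    subjects as the pointwise unit.
    """
    n_draws, _ = loglik.shape
    lpd = logsumexp(loglik, axis=0) - np.log(n_draws)
    penalty = lpd - loglik.mean(axis=0)
    if method == "mean":
        return lpd - penalty, penalty
    if method == "loo":
        import arviz as az

        idata = az.from_dict(
            posterior={"_dummy": np.zeros((1, n_draws))},
            log_likelihood={"obs": loglik[None, :, :]},  # 1 chain
        )
        loo = az.loo(idata, pointwise=True)
        return np.asarray(loo.loo_i), penalty
    raise ValueError("method must be 'mean' or 'loo'")


def model_weights(
    pointwise_logliks: dict[str, np.ndarray],
    n_bootstrap: int = 10_000,
    seed: int = 0,
    group: str = "",
    method: str = "mean",
) -> ModelWeights:
    """Pseudo-BMA+BB weights from per-model (draws x subjects) matrices.

    Adding a constant to every entry of every matrix leaves the
    weights unchanged (only elpd differences matter); a model that is
    better by many nats per subject on every subject takes essentially
    all the weight.
    """
    if not pointwise_logliks:
        raise ValueError("no models supplied")
    subj_counts = {m: ll.shape[1] for m, ll in pointwise_logliks.items()}
    if len(set(subj_counts.values())) != 1:
        raise ValueError(f"subject dimensions differ: {subj_counts}")
    models = list(pointwise_logliks)
    elpd_i = {}
    penalty = {}
    for m in models:
        e, p = elpd_pointwise(pointwise_logliks[m], method=method)
        elpd_i[m] = e
        penalty[m] = float(p.sum())
    if len(models) == 1:
        import warnings

        warnings.warn("single model supplied; weight is trivially 1", stacklevel=2)
        m = models[0]
        return ModelWeights(group, {m: 1.0}, {m: float(elpd_i[m].sum())}, penalty, 0)

    S = len(elpd_i[models[0]])
    E = np.stack([elpd_i[m] for m in models])  # (M, S)
    rng = np.random.default_rng(seed)
    w_bb = rng.dirichlet(np.ones(S), size=n_bootstrap)  # (B, S)
    z = S * w_bb @ E.T  # (B, M) weighted elpd totals
    z -= z.max(axis=1, keepdims=True)
    soft = np.exp(z)
    soft /= soft.sum(axis=1, keepdims=True)
    w = soft.mean(axis=0)
    w = w / w.sum()
    return ModelWeights(
        group,
        dict(zip(models, map(float, w))),
        {m: float(elpd_i[m].sum()) for m in models},
        penalty,
        n_bootstrap,
    )


def recover_models(
    n_per_model: int = 40,
    schedule: TaskSchedule | None = None,
    fit_config: MCMCConfig | None = None,
    seed: int = 0,
    model_set: tuple[str, ...] = DEFAULT_MODEL_SET,
    n_bootstrap: int = 10_000,
) -> pd.DataFrame:
    """Simulate-and-refit confusion matrix over the candidate models.

    For each generating model: simulate ``n_per_model`` synthetic
    participants (parameters uniform over support), fit every
    candidate model to the synthetic group, and compute the weight
    simplex.  Returns a tidy frame with one row per generator, the
    per-candidate weights, and the winning model; failed fits are
    recorded in the ``error`` column rather than raised.
    """
    from .cohort import recovery_set

    if schedule is None:
        schedule = build_schedule(seed=seed)
    rows = []
    if n_per_model == 0:
        return pd.DataFrame(columns=["generator", *model_set, "winner", "error"])
    ss = np.random.SeedSequence(seed)
    gen_seeds = ss.generate_state(len(model_set))
    for gi, gen in enumerate(model_set):
        cohort, _ = recovery_set(gen, n_per_model, schedule, seed=int(gen_seeds[gi]))
        row: dict = {"generator": gen, "error": ""}
        lls = {}
        try:
            for mi, m in enumerate(model_set):
                cfg = fit_config or MCMCConfig()
                cfg = MCMCConfig(**{**cfg.__dict__, "seed": cfg.seed + 1000 * gi + 17 * mi})
                draws = fit_group(cohort, m, cfg)
                lls[m] = pointwise_loglik(draws, cohort)
            mw = model_weights(
                lls, n_bootstrap=n_bootstrap, seed=int(gen_seeds[gi]) + 1, group=gen
            )
            row.update(mw.weights)
            row["winner"] = mw.winner
        except Exception as exc:  # propagate per cell, not fatally
            row["error"] = f"{type(exc).__name__}: {exc}"
            row["winner"] = ""
        rows.append(row)
    return pd.DataFrame(rows)
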