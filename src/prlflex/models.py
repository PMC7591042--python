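"""Reinforcement-learning value updates, softmax choice, and likelihoods.

Four models of trial-and-error learning on the two-stimulus PRL task,
each extending the Rescorla-Wagner (RW) delta rule:

``RW``
    V_c <- V_c + eta * (O - V_c); only the chosen stimulus updates.
``CU`` (counterfactual update)
    Both stimuli update: the chosen one with the actual prediction
    error, the unchosen one with the counterfactual error against -O,
    exploiting the anti-correlation of the two stimuli.
``RP`` (reward-punishment)
    RW update of the chosen stimulus with separate learning rates for
    rewarding (O > 0) and punishing (O < 0) outcomes.
``EWA_DL`` (experience-weighted attraction, dynamic learning rate)
    Each stimulus carries an experience weight n that grows under decay
    rho (n_c <- n_c * rho + 1) and divides the value update
    (V_c <- (V_c * phi * n_prev + O) / n_new), so the effective
    learning rate shrinks as experience accrues; phi decays past
    payoffs and acts as an inverse learning rate.

Choice follows a softmax on the value difference,
``p(A) = 1 / (1 + exp(beta * (alpha - (V_A - V_B))))``, with value
sensitivity beta in (0, 5) and indifference point alpha in (-0.5, 0.5).

Values are initialised at 0 (unbiased start) and EWA experience
weights at 1, which keeps the first EWA update well defined for every
rho (V_1 = O / (rho + 1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .task import STIMULI, SubjectData

__all__ = [
    "MODEL_IDS",
    "MODEL_PARAMS",
    "PARAM_BOUNDS",
    "ParamVector",
    "LatentState",
    "init_state",
    "update_rw",
    "update_cu",
    "update_rp",
    "update_ewa",
    "choice_prob",
    "sequence_loglik",
    "batch_loglik",
]

MODEL_IDS = ("RW", "CU", "RP", "EWA_DL")

#: Free parameters per model, in canonical order.
MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "RW": ("eta", "beta", "alpha"),
    "CU": ("eta", "beta", "alpha"),
    "RP": ("eta_rew", "eta_pun", "beta", "alpha"),
    "EWA_DL": ("phi", "rho", "beta", "alpha"),
}

#: Support of each parameter. Learning rates and decays live on [0, 1];
#: beta and alpha have open supports enforced by the fitting transforms.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "eta": (0.0, 1.0),
    "eta_rew": (0.0, 1.0),
    "eta_pun": (0.0, 1.0),
    "phi": (0.0, 1.0),
    "rho": (0.0, 1.0),
    "beta": (0.0, 5.0),
    "alpha": (-0.5, 0.5),
}

#: The parameter that indexes the model's learning mechanism, used as
#: the focal quantity in recovery checks and optimality grids.
FOCAL_PARAM: dict[str, str] = {
    "RW": "eta",
    "CU": "eta",
    "RP": "eta_rew",
    "EWA_DL": "phi",
}

_LOG_FLOOR = np.log(1e-12)  # per-trial guard against pathological draws


@dataclass(frozen=True)
class ParamVector:
    """A model's free parameters, validated against their bounds."""

    model_id: str
    params: dict[str, float]

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model_id!r}")
        expected = set(MODEL_PARAMS[self.model_id])
        got = set(self.params)
        if got != expected:
            raise ValueError(
                f"{self.model_id} expects parameters {sorted(expected)}, got {sorted(got)}"
            )
        for name, value in self.params.items():
            lo, hi = PARAM_BOUNDS[name]
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    def to_dict(self) -> dict:
        return {"model_id": self.model_id, **self.params}

    @classmethod
    def from_dict(cls, d: dict) -> "ParamVector":
        d = dict(d)
        model_id = d.pop("model_id")
        return cls(model_id, d)


@dataclass(frozen=True)
class LatentState:
    """Stimulus values (and EWA experience weights), index 0 = A, 1 = B."""

    v: np.ndarray
    n: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))
        if self.n is not None:
            object.__setattr__(self, "n", np.asarray(self.n, dtype=float))


def init_state(model_id: str) -> LatentState:
    """Pre-task state: values at 0; EWA experience weights at 1."""
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}")
    n = np.ones(2) if model_id == "EWA_DL" else None
    return LatentState(v=np.zeros(2), n=n)


def _stim_index(choice) -> int:
    if choice in STIMULI:
        return STIMULI.index(choice)
    if choice in (0, 1):
        return int(choice)
    raise ValueError(f"unknown stimulus {choice!r}")


def _check_rate(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name}={value} outside [0, 1]")


def update_rw(state: LatentState, choice, outcome: float, eta: float) -> LatentState:
    """Delta-rule update of the chosen stimulus only."""
    _check_rate("eta", eta)
    c = _stim_index(choice)
    v = state.v.copy()
    v[c] += eta * (outcome - v[c])
    return replace(state, v=v)


def update_cu(state: LatentState, choice, outcome: float, eta: float) -> LatentState:
    """Counterfactual update: chosen toward O, unchosen toward -O."""
    _check_rate("eta", eta)
    c = _stim_index(choice)
    v = state.v.copy()
    v[c] += eta * (outcome - v[c])
    v[1 - c] += eta * (-outcome - v[1 - c])
    return replace(state, v=v)


def update_rp(
    state: LatentState, choice, outcome: float, eta_rew: float, eta_pun: float
) -> LatentState:
    """Chosen-stimulus update with outcome-sign-specific learning rate."""
    _check_rate("eta_rew", eta_rew)
    _check_rate("eta_pun", eta_pun)
    if outcome == 0:
        raise ValueError("outcome 0 has no defined learning rate branch")
    c = _stim_index(choice)
    v = state.v.copy()
    eta = eta_rew if outcome > 0 else eta_pun
    v[c] += eta * (outcome - v[c])
    return replace(state, v=v)


def update_ewa(
    state: LatentState, choice, outcome: float, phi: float, rho: float
) -> LatentState:
    """Experience-weighted update of the chosen stimulus.

    The unchosen stimulus keeps both its value and its experience
    weight (the weight is frozen, not decayed).
    """
    _check_rate("phi", phi)
    _check_rate("rho", rho)
    if state.n is None:
        raise ValueError("EWA update requires experience weights; use init_state('EWA_DL')")
    c = _stim_index(choice)
    v, n = state.v.copy(), state.n.copy()
    n_prev = n[c]
    n[c] = n_prev * rho + 1.0
    v[c] = (v[c] * phi * n_prev + outcome) / n[c]
    return LatentState(v=v, n=n)


_UPDATES = {
    "RW": lambda s, c, o, p: update_rw(s, c, o, p["eta"]),
    "CU": lambda s, c, o, p: update_cu(s, c, o, p["eta"]),
    "RP": lambda s, c, o, p: update_rp(s, c, o, p["eta_rew"], p["eta_pun"]),
    "EWA_DL": lambda s, c, o, p: update_ewa(s, c, o, p["phi"], p["rho"]),
}


def apply_update(model_id: str, state: LatentState, choice, outcome, params) -> LatentState:
    """Dispatch one trial's value update for the given model."""
    return _UPDATES[model_id](state, choice, outcome, params)


def choice_prob(state: LatentState, beta: float, alpha: float = 0.0) -> float:
    """Softmax probability of choosing stimulus A given the current values."""
    return float(expit(beta * (state.v[0] - state.v[1] - alpha)))


def sequence_loglik(
    data: SubjectData,
    model_id: str,
    params: ParamVector | dict,
    per_trial: bool = False,
):
    """Log-likelihood of a subject's recorded choice sequence.

    Iterates the model state over the recorded choices and outcomes
    (no re-simulation): at each trial the probability of the recorded
    choice under the current values is accumulated in the log domain,
    then the recorded outcome drives the value update.

    Returns the total log-likelihood, or ``(total, per_trial_terms)``
    when ``per_trial`` is true.
    """
    if isinstance(params, ParamVector):
        if params.model_id != model_id:
            raise ValueError("params do not match model_id")
        params = params.params
    arrays = {k: np.asarray(v, dtype=float) for k, v in params.items()}
    total, terms = batch_loglik(
        model_id, arrays, data.choices[None, :], data.outcomes[None, :], per_trial=True
    )
    if per_trial:
        return float(total[0]), terms[0]
    return float(total[0])


def batch_loglik(
    model_id: str,
    params: dict[str, np.ndarray],
    choices: np.ndarray,
    outcomes: np.ndarray,
    per_trial: bool = False,
):
    """Vectorised sequence log-likelihood over subjects and parameter sets.

    Parameters
    ----------
    params : dict of arrays
        Each entry is a scalar or an array broadcastable to a common
        lead shape ending in the subject axis (e.g. ``(n_draws, S)``).
    choices, outcomes : arrays of shape (S, T)
        Recorded choices (0 = A, 1 = B) and outcomes (+1/-1).

    Returns
    -------
    total : array with the broadcast lead shape + (S,)
        Per-subject total log-likelihood.  With ``per_trial=True``,
        also the per-trial terms with a trailing T axis.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}")
    choices = np.asarray(choices)
    outcomes = np.asarray(outcomes, dtype=float)
    if choices.shape != outcomes.shape or choices.ndim != 2:
        raise ValueError("choices and outcomes must share shape (S, T)")
    S, T = choices.shape
    p = {k: np.asarray(v, dtype=float) for k, v in params.items()}
    lead = np.broadcast_shapes(*(a.shape for a in p.values()), (S,))
    beta, alpha = p["beta"], p["alpha"]

    va = np.zeros(lead)
    vb = np.zeros(lead)
    if model_id == "EWA_DL":
        na = np.ones(lead)
        nb = np.ones(lead)
    out = np.zeros(lead + (T,)) if per_trial else None
    total = np.zeros(lead)

    for t in range(T):
        chose_a = choices[:, t] == 0  # broadcasts over lead axes
        o = outcomes[:, t]
        p_a = expit(beta * (va - vb - alpha))
        p_choice = np.where(chose_a, p_a, 1.0 - p_a)
        term = np.maximum(np.log(np.maximum(p_choice, 1e-300)), _LOG_FLOOR)
        total = total + term
        if per_trial:
            out[..., t] = term
        if model_id in ("RW", "CU"):
            eta = p["eta"]
            va_new = va + eta * (o - va)
            vb_new = vb + eta * (o - vb)
            if model_id == "CU":
                va = np.where(chose_a, va_new, va + eta * (-o - va))
                vb = np.where(chose_a, vb + eta * (-o - vb), vb_new)
            else:
                va = np.where(chose_a, va_new, va)
                vb = np.where(chose_a, vb, vb_new)
        elif model_id == "RP":
            eta = np.where(o > 0, p["eta_rew"], p["eta_pun"])
            va = np.where(chose_a, va + eta * (o - va), va)
            vb = np.where(chose_a, vb, vb + eta * (o - vb))
        else:  # EWA_DL
            phi, rho = p["phi"], p["rho"]
            na_new = np.where(chose_a, na * rho + 1.0, na)
            nb_new = np.where(chose_a, nb, nb * rho + 1.0)
            va = np.where(chose_a, (va * phi * na + o) / na_new, va)
            vb = np.where(chose_a, vb, (vb * phi * nb + o) / nb_new)
            na, nb = na_new, nb_new

    if per_trial:
        return total, out
    return total
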