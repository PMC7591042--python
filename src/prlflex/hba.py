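"""Hierarchical Bayesian estimation of the RL models, per group.

Each group (e.g. TD children) is fit with a two-level model: on an
unconstrained ("raw") scale, subject-level parameters are exchangeable
draws from a group Gaussian,

    mu_p ~ Normal(0, 1)          (group mean, raw scale)
    sigma_p ~ HalfNormal(s)      (group SD, raw scale)
    raw_{i,p} ~ Normal(mu_p, sigma_p)

and bounded natural-scale parameters are obtained by squashing each
raw coordinate to its support: learning rates and decays via the
logistic function, beta via 5 * logistic, alpha via logistic - 1/2
(a probit-style squashing is available as a config switch).  The
group-level regularization shrinks noisy individual estimates toward
the group mean.

Posterior sampling uses a purpose-built Metropolis-within-Gibbs
scheme that exploits the hierarchy's conditional structure: group
means are updated by conjugate Gibbs steps, group SDs by random-walk
Metropolis on log sigma, and each subject's raw parameter block by a
jointly proposed random-walk Metropolis step — all subjects and all
chains advance in lockstep through one vectorised likelihood
evaluation per sweep.  Proposal scales adapt during warmup only.
Convergence is checked with split-R-hat and effective sample size
(via arviz) on the group-level parameters; fitting fails loudly
rather than returning silently bad draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit, ndtr, ndtri

from .models import MODEL_IDS, MODEL_PARAMS, ParamVector, batch_loglik
from .task import SubjectData

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "ConvergenceError",
    "fit_group",
    "fit_subject_mle",
    "pointwise_loglik",
]


class ConvergenceError(RuntimeError):
    """MCMC diagnostics exceeded their thresholds.

    Carries the offending parameter names and their split-R-hat values.
    """

    def __init__(self, message: str, offending: dict[str, float]):
        super().__init__(message)
        self.offending = offending


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``draws`` is the retained count per chain after thinning; the
    sampler runs ``draws * thin`` post-warmup iterations per chain, so
    defaults retain 4 x 1000 = 4,000 draws.  ``sigma_prior_scale`` is
    the half-Normal scale on raw-scale group SDs.  ``transform``
    selects the raw-to-natural squashing ("logistic" or "probit").
    """

    chains: int = 4
    draws: int = 1000
    warmup: int = 1500
    thin: int = 3
    sweeps: int = 2
    seed: int = 0
    sigma_prior_scale: float = 1.0
    transform: str = "logistic"
    rhat_max: float = 1.1
    check_convergence: bool = True

    def __post_init__(self) -> None:
        if self.transform not in ("logistic", "probit"):
            raise ValueError("transform must be 'logistic' or 'probit'")


def _squash(raw: np.ndarray, transform: str) -> np.ndarray:
    return expit(raw) if transform == "logistic" else ndtr(raw)


def _unsquash(u: np.ndarray, transform: str) -> np.ndarray:
    return logit(u) if transform == "logistic" else ndtri(u)


def transform_params(
    raw: np.ndarray, param_names: tuple[str, ...], transform: str = "logistic"
) -> np.ndarray:
    """Map raw-scale draws (..., P) onto each parameter's support."""
    u = _squash(raw, transform)
    out = np.empty_like(u)
    for j, name in enumerate(param_names):
        if name == "beta":
            out[..., j] = 5.0 * u[..., j]
        elif name == "alpha":
            out[..., j] = u[..., j] - 0.5
        else:  # rates and decays on [0, 1]
            out[..., j] = u[..., j]
    return out


def untransform_params(
    theta: np.ndarray, param_names: tuple[str, ...], transform: str = "logistic"
) -> np.ndarray:
    """Inverse of :func:`transform_params` (natural -> raw scale)."""
    theta = np.asarray(theta, dtype=float)
    u = np.empty_like(theta)
    for j, name in enumerate(param_names):
        if name == "beta":
            u[..., j] = theta[..., j] / 5.0
        elif name == "alpha":
            u[..., j] = theta[..., j] + 0.5
        else:
            u[..., j] = theta[..., j]
    eps = 1e-9
    return _unsquash(np.clip(u, eps, 1 - eps), transform)


@dataclass
class PosteriorDraws:
    """MCMC draws for one group x model fit.

    Group-level arrays are raw-scale with shape (chains, draws, P);
    ``subject`` holds natural-scale per-subject draws with shape
    (chains, draws, S, P).
    """

    group: str
    model_id: str
    param_names: tuple[str, ...]
    subject_ids: tuple[str, ...]
    mu: np.ndarray
    sigma: np.ndarray
    subject: np.ndarray
    diagnostics: pd.DataFrame
    config: MCMCConfig

    @property
    def n_draws(self) -> int:
        """Total retained draws across chains."""
        return self.mu.shape[0] * self.mu.shape[1]

    def subject_draws(self) -> np.ndarray:
        """Natural-scale per-subject draws, flattened to (n_draws, S, P)."""
        c, d, s, p = self.subject.shape
        return self.subject.reshape(c * d, s, p)

    def group_mean_draws(self) -> np.ndarray:
        """Draws of the group mean parameter on the natural scale.

        The group-level summary reported for a cohort is the mean of
        its members' parameters, so each posterior draw contributes
        the subject-average of the natural-scale parameters,
        shape (n_draws, P).
        """
        return self.subject_draws().mean(axis=1)

    def subject_param_table(self) -> pd.DataFrame:
        """Posterior mean (SD) of each subject's parameters."""
        draws = self.subject_draws()
        rows = []
        for i, sid in enumerate(self.subject_ids):
            row = {"subject_id": sid}
            for j, name in enumerate(self.param_names):
                row[name] = draws[:, i, j].mean()
                row[f"{name}_sd"] = draws[:, i, j].std()
            rows.append(row)
        return pd.DataFrame(rows)

    def to_inferencedata(self):
        """Package group-level draws as an arviz InferenceData."""
        import arviz as az

        data = {f"mu_{n}": self.mu[..., j] for j, n in enumerate(self.param_names)}
        data.update(
            {f"sigma_{n}": self.sigma[..., j] for j, n in enumerate(self.param_names)}
        )
        return az.from_dict(posterior=data)


def _halfnormal_logpdf(x: np.ndarray, scale: float) -> np.ndarray:
    return np.where(x > 0, -0.5 * (x / scale) ** 2, -np.inf)


def fit_group(
    cohort_subset: list[SubjectData],
    model_id: str,
    mcmc_config: MCMCConfig | None = None,
) -> PosteriorDraws:
    """Fit one model to one group's subjects by MCMC.

    All subjects must carry the same (diagnosis, age_group) label and
    there must be at least two of them (the hierarchy needs a group).
    Identical data and config yield identical draws.

    Raises
    ------
    ConvergenceError
        If any monitored split-R-hat exceeds ``config.rhat_max``.
    """
    cfg = mcmc_config or MCMCConfig()
    if len(cohort_subset) < 2:
        raise ValueError("hierarchical fit needs at least 2 subjects")
    labels = {(s.diagnosis, s.age_group) for s in cohort_subset}
    if len(labels) != 1:
        raise ValueError(f"subjects span multiple groups: {sorted(labels)}")
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}")

    names = MODEL_PARAMS[model_id]
    P = len(names)
    S = len(cohort_subset)
    C = cfg.chains
    choices = np.stack([s.choices for s in cohort_subset])
    outcomes = np.stack([s.outcomes for s in cohort_subset])
    rng = np.random.default_rng(cfg.seed)

    def data_loglik(raw: np.ndarray) -> np.ndarray:
        """Summed per-subject log-likelihood; raw shape (C, S, P) -> (C, S)."""
        theta = transform_params(raw, names, cfg.transform)
        params = {n: theta[..., j] for j, n in enumerate(names)}
        return batch_loglik(model_id, params, choices, outcomes)

    # --- initial state ----------------------------------------------------
    mu = rng.normal(0.0, 0.5, size=(C, P))
    sigma = np.abs(rng.normal(0.5, 0.1, size=(C, P)))
    raw = mu[:, None, :] + sigma[:, None, :] * rng.normal(size=(C, S, P))
    ll = data_loglik(raw)

    step_subj = np.full((C, S), 0.5)  # RW proposal scale per subject block
    # diagonal proposal shape per (chain, subject, parameter), learned
    # during warmup from an EMA of the chain's own spread
    ema_mean = raw.copy()
    ema_var = np.full((C, S, P), 0.25)
    step_sigma = np.full((C, P), 0.5)
    step_shift = np.full(C, 0.2)  # non-centered translation of (mu, raw)
    step_scale = np.full((C, P), 0.3)  # non-centered rescaling of (sigma, raw)
    accept_target_subj = 0.30
    accept_target_sigma = 0.44
    accept_target_block = 0.25

    n_post = cfg.draws * cfg.thin
    total_iters = cfg.warmup + n_post
    keep_mu = np.empty((C, cfg.draws, P))
    keep_sigma = np.empty((C, cfg.draws, P))
    keep_subject = np.empty((C, cfg.draws, S, P))
    kept = 0

    for it in range(total_iters):
        warm = it < cfg.warmup
        # (1) conjugate Gibbs update of group means
        prec = 1.0 + S / sigma**2
        mean = (raw.sum(axis=1) / sigma**2) / prec
        mu = mean + rng.normal(size=(C, P)) / np.sqrt(prec)

        # (2) random-walk Metropolis on log sigma (no data term needed)
        prop = sigma * np.exp(step_sigma * rng.normal(size=(C, P)))
        dev = raw - mu[:, None, :]
        def sigma_logpost(s):
            return (
                -S * np.log(s)
                - 0.5 * (dev**2).sum(axis=1) / s**2
                + _halfnormal_logpdf(s, cfg.sigma_prior_scale)
                + np.log(s)  # Jacobian of the log-scale walk
            )
        log_acc = sigma_logpost(prop) - sigma_logpost(sigma)
        acc = np.log(rng.random((C, P))) < log_acc
        sigma = np.where(acc, prop, sigma)
        if warm:
            step_sigma *= np.exp(0.05 * (acc - accept_target_sigma))
            step_sigma = np.clip(step_sigma, 1e-3, 5.0)

        # (2b) interweaved non-centered moves: with the standardized
        # deviations held fixed, translate (mu, raw) together, then
        # rescale (sigma, raw) together.  These block moves cut
        # through the funnel that appears when a group SD is small.
        delta = step_shift[:, None] * rng.normal(size=(C, P))
        prop_raw = raw + delta[:, None, :]
        ll_prop = data_loglik(prop_raw)
        prop_mu = mu + delta
        log_acc = (
            (ll_prop - ll).sum(axis=1)
            - 0.5 * (prop_mu**2 - mu**2).sum(axis=1)  # mu ~ N(0,1) prior
        )
        acc_c = np.log(rng.random(C)) < log_acc
        mu = np.where(acc_c[:, None], prop_mu, mu)
        raw = np.where(acc_c[:, None, None], prop_raw, raw)
        ll = np.where(acc_c[:, None], ll_prop, ll)
        if warm:
            step_shift *= np.exp(0.05 * (acc_c - accept_target_block))
            step_shift = np.clip(step_shift, 1e-3, 5.0)

        for p_idx in range(P):
            eps_p = (raw[:, :, p_idx] - mu[:, None, p_idx]) / sigma[:, None, p_idx]
            factor = np.exp(step_scale[:, p_idx] * rng.normal(size=C))
            prop_sigma_p = sigma[:, p_idx] * factor
            prop_raw = raw.copy()
            prop_raw[:, :, p_idx] = mu[:, None, p_idx] + prop_sigma_p[:, None] * eps_p
            ll_prop = data_loglik(prop_raw)
            log_acc = (
                (ll_prop - ll).sum(axis=1)
                + _halfnormal_logpdf(prop_sigma_p, cfg.sigma_prior_scale)
                - _halfnormal_logpdf(sigma[:, p_idx], cfg.sigma_prior_scale)
                + np.log(factor)  # Jacobian of the log-scale walk
            )
            acc_c = np.log(rng.random(C)) < log_acc
            sigma[:, p_idx] = np.where(acc_c, prop_sigma_p, sigma[:, p_idx])
            raw = np.where(acc_c[:, None, None], prop_raw, raw)
            ll = np.where(acc_c[:, None], ll_prop, ll)
            if warm:
                step_scale[:, p_idx] *= np.exp(0.05 * (acc_c - accept_target_block))
        if warm:
            step_scale = np.clip(step_scale, 1e-3, 5.0)
        dev = raw - mu[:, None, :]

        # (3) per-subject block Metropolis, all subjects in lockstep
        prop_sd = step_subj[..., None] * np.sqrt(ema_var)
        for _ in range(cfg.sweeps):
            prop_raw = raw + prop_sd * rng.normal(size=(C, S, P))
            ll_prop = data_loglik(prop_raw)
            prior_diff = (
                -0.5 * ((prop_raw - mu[:, None, :]) ** 2 - dev**2) / sigma[:, None, :] ** 2
            ).sum(axis=2)
            log_acc = ll_prop - ll + prior_diff
            acc = np.log(rng.random((C, S))) < log_acc
            raw = np.where(acc[..., None], prop_raw, raw)
            ll = np.where(acc, ll_prop, ll)
            dev = raw - mu[:, None, :]
            if warm:
                step_subj *= np.exp(0.05 * (acc - accept_target_subj))
                step_subj = np.clip(step_subj, 1e-3, 5.0)
        if warm:
            ema_mean += 0.02 * (raw - ema_mean)
            ema_var += 0.02 * ((raw - ema_mean) ** 2 - ema_var)
            ema_var = np.clip(ema_var, 1e-4, 25.0)

        if not warm and (it - cfg.warmup) % cfg.thin == cfg.thin - 1:
            keep_mu[:, kept] = mu
            keep_sigma[:, kept] = sigma
            keep_subject[:, kept] = transform_params(raw, names, cfg.transform)
            kept += 1

    assert kept == cfg.draws

    diagnostics = _diagnose(keep_mu, keep_sigma, names)
    group = f"{cohort_subset[0].diagnosis}-{cohort_subset[0].age_group}"
    draws = PosteriorDraws(
        group=group,
        model_id=model_id,
        param_names=names,
        subject_ids=tuple(s.subject_id for s in cohort_subset),
        mu=keep_mu,
        sigma=keep_sigma,
        subject=keep_subject,
        diagnostics=diagnostics,
        config=cfg,
    )
    if cfg.check_convergence:
        bad = diagnostics[diagnostics["rhat"] > cfg.rhat_max]
        if len(bad):
            raise ConvergenceError(
                f"{group}/{model_id}: split-R-hat above {cfg.rhat_max} for "
                f"{', '.join(bad['param'])}",
                offending=dict(zip(bad["param"], bad["rhat"])),
            )
    return draws


def _diagnose(
    keep_mu: np.ndarray, keep_sigma: np.ndarray, names: tuple[str, ...]
) -> pd.DataFrame:
    """Split-R-hat and bulk ESS per monitored group-level parameter."""
    import arviz as az

    rows = []
    for j, n in enumerate(names):
        for kind, arr in (("mu", keep_mu), ("sigma", keep_sigma)):
            rows.append(
                {
                    "param": f"{kind}_{n}",
                    "rhat": float(az.rhat(arr[..., j])),
                    "ess": float(az.ess(arr[..., j])),
                }
            )
    return pd.DataFrame(rows)


def fit_subject_mle(
    data: SubjectData,
    model_id: str,
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[ParamVector, float]:
    """Per-subject maximum likelihood, multi-start, on the raw scale.

    Serves as a non-Bayesian oracle for recovery tests; returns the
    best ParamVector (natural scale) and its log-likelihood.
    """
    names = MODEL_PARAMS[model_id]
    choices = data.choices[None, :]
    outcomes = data.outcomes[None, :]
    rng = np.random.default_rng(seed)

    def negloglik(raw_flat: np.ndarray) -> float:
        theta = transform_params(raw_flat[None, :], names, "logistic")
        params = {n: theta[..., j] for j, n in enumerate(names)}
        return -float(batch_loglik(model_id, params, choices, outcomes)[0])

    best = None
    for _ in range(max(1, n_restarts)):
        x0 = rng.normal(0.0, 1.0, size=len(names))
        res = optimize.minimize(negloglik, x0, method="Nelder-Mead",
                                options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all MLE restarts failed")
    theta = transform_params(best.x[None, :], names, "logistic")[0]
    # keep strictly inside open supports
    params = {}
    for j, n in enumerate(names):
        params[n] = float(theta[j])
    return ParamVector(model_id, params), -float(best.fun)


def pointwise_loglik(
    draws: PosteriorDraws,
    cohort_subset: list[SubjectData],
    chunk: int = 500,
) -> np.ndarray:
    """Per-draw, per-subject log-likelihood matrix (n_draws, S).

    Entry (s, i) evaluates subject i's recorded sequence at draw s of
    that subject's own posterior parameters.
    """
    ids = tuple(s.subject_id for s in cohort_subset)
    if ids != draws.subject_ids:
        raise ValueError("cohort subjects do not match the posterior draws")
    choices = np.stack([s.choices for s in cohort_subset])
    outcomes = np.stack([s.outcomes for s in cohort_subset])
    theta = draws.subject_draws()  # (n_draws, S, P)
    n = theta.shape[0]
    out = np.empty((n, len(cohort_subset)))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        params = {
            name: theta[lo:hi, :, j] for j, name in enumerate(draws.param_names)
        }
        out[lo:hi] = batch_loglik(draws.model_id, params, choices, outcomes)
    return out
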