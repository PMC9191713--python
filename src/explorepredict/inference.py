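"""Model fitting and comparison.

Each model is fitted to one session's 120 state predictions by penalized
maximum likelihood (MAP).  Free parameters are optimized in an
unconstrained space — logistic transform for learning rates, log for the
sigmoid slope and inverse temperature, identity for the bias — with an
independent Normal(0, 1.5) prior on each transformed parameter.  The
optimizer is derivative-free (Nelder-Mead) restarted from seeded
latin-hypercube points.  BIC is computed from the likelihood term at the
MAP optimum with n = number of state predictions.

Group-level comparison uses per-agent best-BIC assignment plus
random-effects Bayesian model selection treating −BIC/2 as an approximate
log model evidence: a variational Dirichlet scheme estimates population
model frequencies, and exceedance probabilities are computed by Monte
Carlo sampling from the Dirichlet posterior.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma
from scipy.stats import qmc

from . import _replay
from .learners import FREE_PARAMS, MODELS, ModelParams, n_free_params
from .task_env import SessionData, TaskRules

RANDOM_MODEL = "random"  # zero-parameter guessing baseline

_EPS = 1e-12


# ---------------------------------------------------------------------------
# parameter transforms
# ---------------------------------------------------------------------------
_TRANSFORMS = {
    "alpha": "logistic",
    "alpha_omega": "logistic",
    "beta_omega": "log",
    "bias_omega": "identity",
    "beta_choice": "log",
}


def to_unconstrained(params: ModelParams, model_id: str) -> np.ndarray:
    """Map the model's free parameters to unconstrained fitting space."""
    x = []
    for name in FREE_PARAMS[model_id]:
        v = getattr(params, name)
        kind = _TRANSFORMS[name]
        if kind == "logistic":
            v = min(max(v, _EPS), 1.0 - _EPS)
            x.append(math.log(v / (1.0 - v)))
        elif kind == "log":
            x.append(math.log(max(v, _EPS)))
        else:
            x.append(v)
    return np.array(x)


def from_unconstrained(x: np.ndarray, model_id: str) -> ModelParams:
    """Inverse of :func:`to_unconstrained` (unused fields left at defaults)."""
    kwargs = {}
    for name, xi in zip(FREE_PARAMS[model_id], x):
        kind = _TRANSFORMS[name]
        if kind == "logistic":
            kwargs[name] = 1.0 / (1.0 + math.exp(-xi))
        elif kind == "log":
            kwargs[name] = math.exp(min(xi, 30.0))
        else:
            kwargs[name] = xi
    return ModelParams(**kwargs)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------
def session_nll(model_id: str, params: ModelParams, session: SessionData,
                rules: Optional[TaskRules] = None, *,
                eq5_actor_max: bool = False,
                feedback_mode: str = "asymmetric",
                _encoded: Optional[dict] = None) -> float:
    """Negative log-likelihood (nats) of a session's state predictions.

    Replays the full event stream (exploratory trials and reinforced state
    predictions drive learning) and accumulates −log softmax probability of
    the logged island choice over the state-prediction trials only.
    """
    if model_id == RANDOM_MODEL:
        n_pred = sum(1 for r in session.records if r.trial_type == "state_pred")
        return n_pred * math.log(3.0)
    _validate_params(model_id, params)
    enc = _encoded if _encoded is not None else _replay.encode_session(session)
    return _replay.nll_from_encoded(model_id, params, enc,
                                    eq5_actor_max=eq5_actor_max,
                                    feedback_mode=feedback_mode)


def _validate_params(model_id: str, params: ModelParams) -> None:
    if model_id not in MODELS:
        raise ValueError(f"unknown model {model_id!r}")
    for name in FREE_PARAMS[model_id]:
        v = getattr(params, name)
        if _TRANSFORMS[name] == "logistic" and not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
        if _TRANSFORMS[name] == "log" and v < 0.0:
            raise ValueError(f"{name}={v} must be nonnegative")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class FitConfig:
    """MAP fitting configuration."""

    n_starts: int = 10
    prior_sd: float = 1.5       # Normal(0, prior_sd) on each transformed param
    start_scale: float = 2.0    # LHS starts drawn in [-start_scale, start_scale]^k
    seed: int = 0
    xatol: float = 1e-6
    fatol: float = 1e-6
    maxiter: int = 2000
    eq5_actor_max: bool = False
    feedback_mode: str = "asymmetric"


@dataclass
class FitResult:
    """Per-session optimum for one model."""

    model_id: str
    params_hat: ModelParams
    nll: float          # likelihood term at the optimum (nats)
    penalized: float    # nll + negative log prior at the optimum
    bic: float
    n_obs: int
    k: int
    n_starts: int
    converged: bool
    seed: int


def fit_session(model_id: str, session: SessionData,
                rules: Optional[TaskRules] = None,
                fit_config: Optional[FitConfig] = None) -> FitResult:
    """Fit one model to one session by multistart MAP optimization."""
    cfg = fit_config or FitConfig()
    n_obs = sum(1 for r in session.records if r.trial_type == "state_pred")
    if model_id == RANDOM_MODEL:
        nll = n_obs * math.log(3.0)
        return FitResult(RANDOM_MODEL, ModelParams(), nll, nll,
                         bic=2.0 * nll, n_obs=n_obs, k=0, n_starts=0,
                         converged=True, seed=cfg.seed)
    enc = _replay.encode_session(session)
    k = n_free_params(model_id)

    def objective(x: np.ndarray) -> float:
        params = from_unconstrained(x, model_id)
        nll = _replay.nll_from_encoded(model_id, params, enc,
                                       eq5_actor_max=cfg.eq5_actor_max,
                                       feedback_mode=cfg.feedback_mode)
        prior = 0.5 * float(np.sum((x / cfg.prior_sd) ** 2))
        return nll + prior

    sampler = qmc.LatinHypercube(d=k, seed=cfg.seed)
    starts = cfg.start_scale * (2.0 * sampler.random(cfg.n_starts) - 1.0)
    best = None
    converged = False
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": cfg.xatol, "fatol": cfg.fatol,
                                "maxiter": cfg.maxiter})
        converged = converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params_hat = from_unconstrained(best.x, model_id)
    nll = _replay.nll_from_encoded(model_id, params_hat, enc,
                                   eq5_actor_max=cfg.eq5_actor_max,
                                   feedback_mode=cfg.feedback_mode)
    bic = k * math.log(n_obs) + 2.0 * nll
    return FitResult(model_id, params_hat, nll, float(best.fun), bic,
                     n_obs=n_obs, k=k, n_starts=cfg.n_starts,
                     converged=converged, seed=cfg.seed)


# ---------------------------------------------------------------------------
# group-level comparison
# ---------------------------------------------------------------------------
@dataclass
class ComparisonTable:
    """Group model-comparison summary."""

    bic: pd.DataFrame                 # agents × models
    best_model: pd.Series             # per-agent winner (ties → fewer params)
    group_bic: pd.Series              # summed BIC per model
    delta_bic_random: pd.Series       # random-baseline BIC sum − model BIC sum
    frequencies: pd.Series            # estimated population model frequencies
    exceedance: pd.Series             # exceedance probabilities
    dirichlet_alpha: pd.Series
    seed: int = 0


def dirichlet_bms(log_evidence: np.ndarray, alpha0: float = 1.0,
                  n_samples: int = 100_000, seed: int = 0,
                  tol: float = 1e-8, max_iter: int = 10_000):
    """Random-effects Bayesian model selection over a log-evidence matrix.

    Variational scheme for a Dirichlet(alpha0) prior over population model
    frequencies; exceedance probabilities by Monte Carlo over the Dirichlet
    posterior.  Returns (alpha, frequencies, exceedance).
    """
    L = np.asarray(log_evidence, dtype=float)
    n, K = L.shape
    alpha = np.full(K, alpha0)
    for _ in range(max_iter):
        logu = L + digamma(alpha) - digamma(alpha.sum())
        logu = logu - logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        u /= u.sum(axis=1, keepdims=True)
        new_alpha = alpha0 + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    freq = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=K) / n_samples
    return alpha, freq, xp


def _best_by_bic(row: pd.Series) -> str:
    # ties broken toward the model with fewer free parameters
    order = sorted(row.index, key=lambda m: (row[m], n_free_params(m)))
    return order[0]


def compare_models(fits: dict[str, dict[str, FitResult]],
                   seed: int = 0) -> ComparisonTable:
    """Group-level comparison from per-agent fits of all four models."""
    agents = sorted(fits)
    missing = [(a, m) for a in agents for m in MODELS if m not in fits[a]]
    if missing:
        raise ValueError(f"missing fits: {missing[:5]}")
    bic = pd.DataFrame({m: [fits[a][m].bic for a in agents] for m in MODELS},
                       index=agents)
    best = bic.apply(_best_by_bic, axis=1)
    group = bic.sum(axis=0)
    n_obs = pd.Series({a: fits[a][MODELS[0]].n_obs for a in agents})
    random_bic_sum = float((2.0 * n_obs * math.log(3.0)).sum())
    delta_random = random_bic_sum - group
    alpha, freq, xp = dirichlet_bms(-bic.to_numpy() / 2.0, seed=seed)
    models = list(MODELS)
    return ComparisonTable(
        bic=bic, best_model=best, group_bic=group,
        delta_bic_random=delta_random,
        frequencies=pd.Series(freq, index=models),
        exceedance=pd.Series(xp, index=models),
        dirichlet_alpha=pd.Series(alpha, index=models),
        seed=seed)
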