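"""Estimation for the Q-learning models.

Two routes are provided:

* :func:`fit_mle` — per-subject maximum likelihood on transformed scales
  (logit for learning rates, log for the inverse temperature, capped), best
  of ``n_restarts`` bounded quasi-Newton runs. Deterministic given a seed;
  this is the default path.
* :func:`fit_hierarchical` — a hierarchical Bayesian fit with partial
  pooling: per-subject parameters on the transformed scales are drawn from
  group-level Normal(mu, sigma) distributions with weakly-informative
  hyperpriors (mu ~ Normal(0, 1), sigma ~ HalfNormal(1)). Sampling is
  Metropolis-within-Gibbs: random-walk updates per subject (adapted during
  warmup), a conjugate Gibbs draw for mu, and a random-walk step for
  log sigma. Pointwise per-trial log-likelihoods are retained per draw for
  PSIS-LOO model comparison.

Both sessions are fit independently per subject; the mixed-model stage
treats session as a repeated measure on the resulting estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .qlearn import encode_trials, nll_arrays
from .types import ChoiceTrial, Phase, QParameters, ValidationError

__all__ = ["FitResult", "FitError", "fit_mle", "fit_hierarchical", "fit_cohort_mle",
           "group_trials"]

LN2 = math.log(2.0)


class FitError(RuntimeError):
    """All optimizer restarts failed."""


@dataclass
class FitResult:
    """Per-subject(-session) parameter estimates with pointwise log-likelihoods.

    ``estimates`` maps (subject_id, session) -> QParameters point estimates
    (posterior means for the hierarchical fit). ``pointwise`` maps the same
    key to a log-likelihood vector (MLE; shape n_trials) or matrix
    (hierarchical; shape n_draws x n_trials). ``diagnostics`` carries
    convergence flags and warnings; they are reported, never silently
    dropped.
    """

    model: str
    method: str
    estimates: dict = field(default_factory=dict)
    pointwise: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    posterior: dict = field(default_factory=dict)

    def n_params(self) -> int:
        return 2 if self.model == "single" else 3

    def to_table(self):
        import pandas as pd

        rows = []
        for (sid, session), p in sorted(self.estimates.items()):
            rows.append(
                {
                    "subject_id": sid,
                    "session": session,
                    "alpha_reward": p.alpha_reward,
                    "alpha_punish": p.alpha_punish,
                    "beta": p.beta,
                }
            )
        return pd.DataFrame(rows)


def group_trials(trials: Sequence[ChoiceTrial]) -> dict:
    """Split training trials by (subject, session), preserving order."""
    groups: dict = {}
    for t in trials:
        if t.phase is Phase.TRAIN:
            groups.setdefault((t.subject_id, t.session), []).append(t)
    return groups


def _unpack(x: np.ndarray, model: str, beta_max: float) -> tuple:
    if model == "single":
        a = expit(x[0])
        return a, a, min(math.exp(x[1]), beta_max)
    return expit(x[0]), expit(x[1]), min(math.exp(x[2]), beta_max)


def fit_mle(
    trials: Sequence[ChoiceTrial],
    model: str = "dual",
    n_restarts: int = 4,
    seed: int = 0,
    beta_max: float = 20.0,
) -> FitResult:
    """Maximum-likelihood fit for one subject-session's training trials."""
    if model not in ("dual", "single"):
        raise ValueError(f"unknown model {model!r}")
    if len(trials) < 30:
        raise ValidationError(
            f"need at least 30 training trials to fit, got {len(trials)}"
        )
    chosen, other, outcome = encode_trials(trials)
    n = len(chosen)

    def objective(x):
        ar, ap, b = _unpack(x, model, beta_max)
        total, _ = nll_arrays(chosen, other, outcome, ar, ap, b)
        return total

    rng = np.random.default_rng(seed)
    dim = 2 if model == "single" else 3
    log_beta_hi = math.log(beta_max)
    bounds = [(-7.0, 7.0)] * (dim - 1) + [(math.log(1e-2), log_beta_hi)]
    # one deterministic start at a plausible center (alpha ~ 0.27, beta ~ 5)
    # guards against the degenerate corner optima (extreme alpha, beta at the
    # cap) that pure random restarts occasionally settle into
    starts = [np.array([-1.0] * (dim - 1) + [math.log(5.0)])]
    for _ in range(max(n_restarts - 1, 0)):
        x0 = np.concatenate(
            [rng.normal(-1.0, 1.0, dim - 1), [rng.normal(1.0, 0.7)]]
        )
        x0[-1] = np.clip(x0[-1], bounds[-1][0], bounds[-1][1])
        starts.append(x0)
    best = None
    failures = 0
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun):
            failures += 1
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError(f"all {n_restarts} restarts failed ({failures} non-finite)")

    ar, ap, b = _unpack(best.x, model, beta_max)
    total, pointwise = nll_arrays(chosen, other, outcome, ar, ap, b)
    key = (trials[0].subject_id, trials[0].session)
    # flat likelihood: fit barely beats a coin-flip model (< 0.05 nats/trial),
    # so the parameters are weakly identified
    flat = (n * LN2 - total) / n < 0.05 or b < 0.2
    result = FitResult(model=model, method="mle")
    result.estimates[key] = QParameters(ar, ap, b)
    result.pointwise[key] = pointwise
    result.diagnostics[key] = {
        "nll": total,
        "converged": bool(best.success),
        "flat_likelihood": bool(flat),
        "n_trials": n,
    }
    return result


def fit_cohort_mle(
    trials: Sequence[ChoiceTrial],
    model: str = "dual",
    n_restarts: int = 4,
    seed: int = 0,
    beta_max: float = 20.0,
) -> FitResult:
    """MLE over every subject-session in a trial table.

    Per-subject seeds are derived from the master seed so any subject's fit
    is reproducible in isolation.
    """
    groups = group_trials(trials)
    result = FitResult(model=model, method="mle")
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(groups))
    for (key, sub_trials), stream in zip(sorted(groups.items()), streams):
        sub_seed = int(np.random.default_rng(stream).integers(2**31))
        one = fit_mle(sub_trials, model, n_restarts, sub_seed, beta_max)
        result.estimates.update(one.estimates)
        result.pointwise.update(one.pointwise)
        result.diagnostics.update(one.diagnostics)
    return result


# --- hierarchical fit ------------------------------------------------------


def _subject_nll(enc, x, model, beta_max):
    ar, ap, b = _unpack(x, model, beta_max)
    total, _ = nll_arrays(enc[0], enc[1], enc[2], ar, ap, b)
    return total


def fit_hierarchical(
    trials: Sequence[ChoiceTrial],
    model: str = "dual",
    n_warmup: int = 600,
    n_draws: int = 400,
    n_chains: int = 2,
    seed: int = 0,
    beta_max: float = 20.0,
    rhat_threshold: float = 1.1,
) -> FitResult:
    """Hierarchical Bayesian fit over all subject-sessions.

    Each subject-session's transformed parameters theta_i are partially
    pooled through Normal(mu, sigma) group distributions. Non-convergence
    (split-R-hat on the group means above ``rhat_threshold``) is carried as
    a warning in the diagnostics, never silently dropped.
    """
    if model not in ("dual", "single"):
        raise ValueError(f"unknown model {model!r}")
    groups = group_trials(trials)
    if len(groups) < 2:
        raise ValidationError("hierarchical fit requires at least 2 subject-sessions")
    keys = sorted(groups)
    enc = {k: encode_trials(groups[k]) for k in keys}
    n_sub = len(keys)
    dim = 2 if model == "single" else 3

    chain_mu = []
    chain_theta = []  # per chain: draws x n_sub x dim
    ss = np.random.SeedSequence(seed)
    for chain_stream in ss.spawn(n_chains):
        rng = np.random.default_rng(chain_stream)
        mu = rng.normal(0, 0.2, dim)
        log_sigma = np.full(dim, math.log(0.5))
        theta = np.tile(mu, (n_sub, 1)) + rng.normal(0, 0.1, (n_sub, dim))
        cur_nll = np.array(
            [_subject_nll(enc[k], theta[i], model, beta_max) for i, k in enumerate(keys)]
        )
        step = np.full(n_sub, 0.3)
        sig_step = 0.3
        mus, thetas = [], []
        n_iter = n_warmup + n_draws
        accept = np.zeros(n_sub)
        for it in range(n_iter):
            sigma = np.exp(log_sigma)
            # subject-level random-walk Metropolis
            for i in range(n_sub):
                prop = theta[i] + rng.normal(0, step[i], dim)
                prop_nll = _subject_nll(enc[keys[i]], prop, model, beta_max)
                logr = (
                    cur_nll[i]
                    - prop_nll
                    - 0.5 * np.sum(((prop - mu) / sigma) ** 2)
                    + 0.5 * np.sum(((theta[i] - mu) / sigma) ** 2)
                )
                if math.log(rng.random()) < logr:
                    theta[i] = prop
                    cur_nll[i] = prop_nll
                    accept[i] += 1
            # Gibbs draw for mu: Normal(0,1) prior, Normal(mu, sigma) likelihood
            prec = n_sub / sigma**2 + 1.0
            mean = (theta.sum(axis=0) / sigma**2) / prec
            mu = rng.normal(mean, 1.0 / np.sqrt(prec))
            # random-walk on log sigma with HalfNormal(1) prior (+ Jacobian)
            prop_ls = log_sigma + rng.normal(0, sig_step, dim)
            for d in range(dim):
                def sigma_logpost(ls):
                    s = math.exp(ls)
                    ll = -n_sub * ls - 0.5 * np.sum((theta[:, d] - mu[d]) ** 2) / s**2
                    return ll - 0.5 * s**2 + ls  # prior + Jacobian
                if math.log(rng.random()) < sigma_logpost(prop_ls[d]) - sigma_logpost(
                    log_sigma[d]
                ):
                    log_sigma[d] = prop_ls[d]
            # warmup adaptation toward ~30% subject-level acceptance
            if it < n_warmup and (it + 1) % 50 == 0:
                rate = accept / 50.0
                step *= np.where(rate < 0.2, 0.7, np.where(rate > 0.45, 1.4, 1.0))
                accept[:] = 0.0
            if it >= n_warmup:
                mus.append(mu.copy())
                thetas.append(theta.copy())
        chain_mu.append(np.array(mus))
        chain_theta.append(np.array(thetas))

    mu_draws = np.stack(chain_mu)  # chains x draws x dim
    theta_draws = np.concatenate(chain_theta)  # total draws x n_sub x dim

    import arviz as az

    rhat = az.rhat(az.convert_to_dataset(mu_draws, group="posterior"))
    rhat_max = float(np.max(rhat["x"].values))

    result = FitResult(model=model, method="hierarchical")
    result.posterior["mu"] = mu_draws
    result.posterior["theta"] = theta_draws
    result.posterior["keys"] = keys
    warn = rhat_max > rhat_threshold
    for i, k in enumerate(keys):
        mean_theta = theta_draws[:, i, :].mean(axis=0)
        ar, ap, b = _unpack(mean_theta, model, beta_max)
        result.estimates[k] = QParameters(ar, ap, b)
        draws_ll = np.empty((theta_draws.shape[0], len(enc[k][0])))
        for j in range(theta_draws.shape[0]):
            arj, apj, bj = _unpack(theta_draws[j, i, :], model, beta_max)
            _, pw = nll_arrays(enc[k][0], enc[k][1], enc[k][2], arj, apj, bj)
            draws_ll[j] = pw
        result.pointwise[k] = draws_ll
        result.diagnostics[k] = {"n_trials": len(enc[k][0])}
    result.diagnostics["group"] = {
        "rhat_max": rhat_max,
        "converged": not warn,
        "warning": f"split-R-hat {rhat_max:.3f} exceeds {rhat_threshold}" if warn else "",
        "mu_mean": mu_draws.reshape(-1, dim).mean(axis=0).tolist(),
    }
    return result
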