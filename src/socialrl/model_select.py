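"""Leave-one-out model comparison between the single- and dual-rate fits.

For hierarchical fits with posterior draws, the expected log pointwise
predictive density is estimated by Pareto-smoothed importance sampling
(PSIS-LOO); LOOIC = -2 * elpd, lower is better. For MLE fits, which carry no
draws, an information-criterion fallback (AIC) is reported and labeled as
such. The pointwise unit is the trial, matching the likelihood
factorization; grouping by condition and session mirrors how the two
candidate models are compared per group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .fitting import FitResult

__all__ = ["LOOResult", "loo", "loo_from_fit", "compare", "compare_by_group"]


@dataclass
class LOOResult:
    """An elpd estimate and its LOOIC for one model on one observation set."""

    elpd: float
    se: float
    pointwise_elpd: np.ndarray
    kind: str  # "psis_loo" or "aic"
    label: str = ""
    pareto_k: Optional[np.ndarray] = None
    n_params: int = 0

    @property
    def looic(self) -> float:
        return -2.0 * self.elpd

    @property
    def n_obs(self) -> int:
        return len(self.pointwise_elpd)


def loo(log_lik: np.ndarray, label: str = "") -> LOOResult:
    """PSIS-LOO from a draws x observations pointwise log-likelihood matrix."""
    log_lik = np.asarray(log_lik, dtype=float)
    if log_lik.ndim != 2:
        raise ValueError("expected a draws x observations matrix")
    n_draws, n_obs = log_lik.shape
    if n_draws < 2 or n_obs < 1:
        raise ValueError("need at least 2 draws and 1 observation")
    if np.allclose(log_lik.std(axis=0), 0.0):
        raise ValueError(
            "degenerate log-likelihood draws (constant per observation); "
            "PSIS-LOO is undefined — use the AIC fallback for point fits"
        )
    import arviz as az

    idata = az.from_dict(
        posterior={"_dummy": np.zeros((1, n_draws))},
        log_likelihood={"obs": log_lik[np.newaxis, :, :]},
    )
    res = az.loo(idata, pointwise=True)
    return LOOResult(
        elpd=float(res.elpd_loo),
        se=float(res.se),
        pointwise_elpd=np.asarray(res.loo_i.values, dtype=float),
        kind="psis_loo",
        label=label,
        pareto_k=np.asarray(res.pareto_k.values, dtype=float),
    )


def aic(pointwise_loglik: np.ndarray, n_params: int, label: str = "") -> LOOResult:
    """AIC fallback for point (MLE) fits, on the -2 * elpd-like scale.

    The per-parameter penalty is folded into ``elpd`` so that
    ``looic == 2 * nll + 2 * k``; pointwise contributions keep the raw
    log-likelihoods (the penalty is a constant and cancels in paired
    differences).
    """
    pw = np.asarray(pointwise_loglik, dtype=float)
    n = len(pw)
    elpd = float(pw.sum()) - n_params
    se = float(np.sqrt(n * np.var(pw)))
    return LOOResult(elpd, se, pw, kind="aic", label=label, n_params=n_params)


def loo_from_fit(fit: FitResult, keys=None, label: str = "") -> LOOResult:
    """elpd for a fit over the given subject-session keys (default: all).

    Hierarchical fits go through PSIS-LOO on the concatenated draws x trials
    matrices; MLE fits fall back to AIC with one parameter set per
    subject-session.
    """
    keys = sorted(fit.pointwise) if keys is None else sorted(keys)
    blocks = [fit.pointwise[k] for k in keys]
    if not blocks:
        raise ValueError("no pointwise log-likelihoods for the requested keys")
    if fit.method == "hierarchical":
        return loo(np.concatenate(blocks, axis=1), label=label)
    return aic(
        np.concatenate(blocks), n_params=fit.n_params() * len(keys), label=label
    )


@dataclass
class Comparison:
    delta_looic: float
    se_delta: float
    preferred: str
    similar_fit: bool
    label: str = ""


def compare(loo_a: LOOResult, loo_b: LOOResult, name_a="a", name_b="b") -> Comparison:
    """Pairwise comparison; ``preferred`` is the lower-LOOIC model, with a
    similar-fit flag when the difference is within its paired SE."""
    if loo_a.n_obs != loo_b.n_obs:
        raise ValueError(
            f"mismatched observation counts ({loo_a.n_obs} vs {loo_b.n_obs}); "
            "the same observations must underlie both models"
        )
    delta_elpd = loo_a.pointwise_elpd - loo_b.pointwise_elpd
    se_delta = 2.0 * float(np.sqrt(len(delta_elpd) * np.var(delta_elpd)))
    delta_looic = loo_a.looic - loo_b.looic
    preferred = name_a if loo_a.looic <= loo_b.looic else name_b
    return Comparison(
        delta_looic=delta_looic,
        se_delta=se_delta,
        preferred=preferred,
        similar_fit=bool(abs(delta_looic) <= se_delta),
        label=loo_a.label or loo_b.label,
    )


def compare_by_group(fit_a: FitResult, fit_b: FitResult, designs,
                     name_a="a", name_b="b"):
    """Compare two fits separately for each condition x session group."""
    import pandas as pd

    cond = {d.subject_id: d.condition.value for d in designs}
    groups: dict = {}
    for sid, session in fit_a.pointwise:
        groups.setdefault((cond.get(sid, "?"), session), []).append((sid, session))
    rows = []
    for (condition, session), keys in sorted(groups.items()):
        la = loo_from_fit(fit_a, keys, label=f"{condition}/s{session}")
        lb = loo_from_fit(fit_b, keys, label=f"{condition}/s{session}")
        comp = compare(la, lb, name_a, name_b)
        rows.append(
            {
                "condition": condition,
                "session": session,
                f"looic_{name_a}": la.looic,
                f"looic_{name_b}": lb.looic,
                "delta_looic": comp.delta_looic,
                "se_delta": comp.se_delta,
                "preferred": comp.preferred,
                "similar_fit": comp.similar_fit,
                "criterion": la.kind,
            }
        )
    return pd.DataFrame(rows)
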