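"""Mixed-effects inference on fitted quantities.

Three model families mirror the study's analysis stage:

* a linear mixed model predicting learning rates from condition, session,
  and prediction-error valence (all 2- and 3-way interactions) with a random
  intercept per participant;
* a trial-level logistic mixed model predicting test-phase accuracy from
  condition, session, and trial type (choose-reward vs avoid-punish);
* linear mixed models on speech update weights (condition x valence).

Factors are effects-coded (+1/2, -1/2) so the intercept is the grand mean.
Post hoc pairwise comparisons of estimated marginal means use a Tukey
(studentized-range) adjustment; Cohen's d standardizes a contrast by the
total random SD, sqrt(random-intercept variance + residual variance).

Degrees of freedom for the linear mixed model use a between-within
(containment) assignment: coefficients constant within participants test
against participants minus between-parameters, the rest against
observations minus participants minus within-parameters.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelSpec",
    "FittedModel",
    "ContrastResult",
    "fit_lmm",
    "fit_glmm",
    "emm_contrasts",
    "effect_size",
    "report",
]


@dataclass(frozen=True)
class ModelSpec:
    """A mixed-model specification: response, factors, random intercept group.

    ``interactions="all"`` expands every 2-way-and-higher interaction of the
    listed factors; every interaction's constituent main effects are always
    included.
    """

    response: str
    factors: tuple
    group: str = "subject_id"
    interactions: str | tuple = "all"
    link: str = "identity"  # or "logit"

    def terms(self) -> list:
        """Ordered model terms: main effects then interactions."""
        terms = [(f,) for f in self.factors]
        if self.interactions == "all":
            for k in range(2, len(self.factors) + 1):
                terms.extend(itertools.combinations(self.factors, k))
        else:
            for combo in self.interactions:
                combo = tuple(combo)
                for f in combo:
                    if (f,) not in terms:
                        raise ValueError(
                            f"interaction {combo} includes factor {f!r} with no "
                            "main effect"
                        )
                terms.append(combo)
        return terms


def _factor_levels(data: pd.DataFrame, factors: Sequence[str]) -> dict:
    levels = {}
    for f in factors:
        if f not in data.columns:
            raise ValueError(f"factor {f!r} not in data")
        levels[f] = sorted(data[f].astype(str).unique())
    return levels


def _code_factor(values: pd.Series, levels: list) -> np.ndarray:
    """Sum-to-zero (effects) coding; for 2 levels this is +-1/2."""
    k = len(levels)
    if k < 2:
        raise ValueError(f"factor with <2 levels: {levels}")
    idx = values.astype(str).map({lv: i for i, lv in enumerate(levels)})
    if idx.isna().any():
        raise ValueError("unseen factor level")
    cols = np.zeros((len(values), k - 1))
    if k == 2:
        cols[:, 0] = np.where(idx == 0, -0.5, 0.5)
    else:
        for j in range(k - 1):
            cols[idx == j + 1, j] = 1.0
            cols[idx == 0, j] = -1.0
    return cols


def _design_matrix(data: pd.DataFrame, spec: ModelSpec, levels: dict):
    """Build the effects-coded design matrix with named columns."""
    columns = [np.ones((len(data), 1))]
    names = ["Intercept"]
    main_cols: dict = {}
    for f in spec.factors:
        main_cols[f] = _code_factor(data[f], levels[f])
    for term in spec.terms():
        block = main_cols[term[0]]
        label_parts = [[f"{term[0]}" if len(levels[term[0]]) == 2 else
                        f"{term[0]}[{lv}]" for lv in levels[term[0]][1:]]]
        for f in term[1:]:
            nxt = main_cols[f]
            block = np.stack(
                [block[:, i] * nxt[:, j]
                 for i in range(block.shape[1]) for j in range(nxt.shape[1])],
                axis=1,
            )
            label_parts.append(
                [f"{f}" if len(levels[f]) == 2 else f"{f}[{lv}]"
                 for lv in levels[f][1:]]
            )
        term_names = [" x ".join(combo) for combo in itertools.product(*label_parts)]
        columns.append(block)
        names.extend(term_names)
    return np.hstack(columns), names


@dataclass
class FittedModel:
    """Fixed-effect estimates with covariance, variance components, and the
    pieces needed to form estimated marginal means."""

    spec: ModelSpec
    params: np.ndarray
    cov: np.ndarray
    names: list
    levels: dict
    sigma2: float  # residual variance (pi^2/3 for the logit link)
    tau00: float  # random-intercept variance
    n_obs: int
    n_groups: int
    df_map: np.ndarray
    warnings: list = field(default_factory=list)
    summary_table: Optional[pd.DataFrame] = None

    @property
    def icc(self) -> float:
        return self.tau00 / (self.tau00 + self.sigma2)

    def df_for(self, contrast_vector: np.ndarray) -> float:
        """Between-within df: the smallest df among the coefficients the
        contrast touches (conservative for mixed contrasts)."""
        used = np.abs(contrast_vector) > 1e-12
        if not used.any():
            return float(self.n_obs - len(self.params))
        return float(np.min(self.df_map[used]))


def gls_information(X, groups, sigma2, tau):
    """X' V^-1 X for a random-intercept covariance V = sigma2 I + tau J,
    via the Sherman-Morrison closed form per group."""
    A = np.zeros((X.shape[1], X.shape[1]))
    for g in np.unique(groups):
        m = groups == g
        Xg = X[m]
        ng = int(m.sum())
        shrink = tau / (sigma2 + ng * tau)
        sx = Xg.sum(axis=0)
        A += (Xg.T @ Xg - shrink * np.outer(sx, sx)) / sigma2
    return A


def _between_within_df(X, groups, names):
    """Containment df per coefficient."""
    df_map = np.empty(X.shape[1])
    group_ids = pd.Series(groups).astype(str).values
    uniq = pd.unique(group_ids)
    n_groups = len(uniq)
    n_obs = X.shape[0]
    within = np.zeros(X.shape[1], dtype=bool)
    frame = pd.DataFrame(X)
    grouped_nunique = frame.groupby(group_ids).nunique()
    within = (grouped_nunique > 1).any(axis=0).values
    p_between = int((~within).sum())
    p_within = int(within.sum())
    df_between = max(n_groups - p_between, 1)
    df_within = max(n_obs - n_groups - p_within, 1)
    df_map[~within] = df_between
    df_map[within] = df_within
    return df_map


def _r_squared(X, params, tau00, sigma2):
    var_fixed = float(np.var(X @ params))
    total = var_fixed + tau00 + sigma2
    return var_fixed / total, (var_fixed + tau00) / total


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Linear mixed model with a participant random intercept.

    The summary table mirrors the estimate / CI / t(df) / p layout, plus a
    random-effects block (sigma^2, tau00, ICC, marginal and conditional R^2).
    A singular fit (random-intercept variance estimated at zero) is carried
    as a warning on the result.
    """
    import statsmodels.api as sm

    cols = [spec.response, spec.group, *spec.factors]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data is missing column(s): {missing}")
    data = data.dropna(subset=cols).reset_index(drop=True)
    levels = _factor_levels(data, spec.factors)
    X, names = _design_matrix(data, spec, levels)
    y = data[spec.response].astype(float).values
    groups = data[spec.group].astype(str).values

    warns: list = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.MixedLM(y, X, groups=groups)
        fit = None
        for method in ("bfgs", "powell", "nm"):
            try:
                fit = model.fit(reml=True, method=method)
            except np.linalg.LinAlgError:
                continue
            break
        if fit is None:
            raise np.linalg.LinAlgError(
                "mixed-model optimization failed under every optimizer"
            )
        for w in caught:
            warns.append(str(w.message))

    params = np.asarray(fit.fe_params)
    sigma2 = float(fit.scale)
    tau00 = float(np.asarray(fit.cov_re)[0, 0])
    # model-based covariance (X' V^-1 X)^-1 at the estimated components;
    # MixedLM's Hessian-based one degrades when tau sits near the boundary
    cov = np.linalg.inv(gls_information(X, groups, sigma2, tau00))
    if tau00 <= 1e-10 or any("boundary" in w for w in warns):
        warns.append("singular fit: random-intercept variance at the boundary")
    df_map = _between_within_df(X, groups, names)

    se = np.sqrt(np.diag(cov))
    tvals = params / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df_map)
    tcrit = stats.t.ppf(0.975, df_map)
    r2m, r2c = _r_squared(X, params, tau00, sigma2)
    table = pd.DataFrame(
        {
            "term": names,
            "estimate": params,
            "ci_low": params - tcrit * se,
            "ci_high": params + tcrit * se,
            "t": tvals,
            "df": df_map,
            "p": pvals,
        }
    )
    table.attrs["random_effects"] = {
        "sigma2": sigma2,
        "tau00": tau00,
        "icc": tau00 / (tau00 + sigma2),
        "n_obs": len(y),
        "n_groups": len(np.unique(groups)),
        "r2_marginal": r2m,
        "r2_conditional": r2c,
    }
    return FittedModel(
        spec=spec,
        params=params,
        cov=cov,
        names=names,
        levels=levels,
        sigma2=sigma2,
        tau00=tau00,
        n_obs=len(y),
        n_groups=len(np.unique(groups)),
        df_map=df_map,
        warnings=warns,
        summary_table=table,
    )


def fit_glmm(data: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Logistic mixed model (random intercept) on a binary response.

    Fit by variational Bayes; fixed effects are reported as odds ratios with
    z = posterior mean / posterior sd. The residual variance on the latent
    scale is the logistic constant pi^2 / 3. Complete separation shows up as
    extreme posterior means and is carried as a warning.
    """
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    if spec.link != "logit":
        raise ValueError("fit_glmm requires a logit-link spec")
    data = data.dropna(subset=[spec.response, spec.group, *spec.factors])
    data = data.reset_index(drop=True)
    y = data[spec.response].astype(float).values
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("logit-link response must be binary 0/1")
    levels = _factor_levels(data, spec.factors)
    X, names = _design_matrix(data, spec, levels)
    groups = data[spec.group].astype(str).values
    _, group_idx = np.unique(groups, return_inverse=True)
    n_groups = group_idx.max() + 1
    import scipy.sparse as sp

    exog_vc = sp.csr_matrix(
        (np.ones(len(y)), (np.arange(len(y)), group_idx)), shape=(len(y), n_groups)
    )
    ident = np.zeros(n_groups, dtype=int)
    model = BinomialBayesMixedGLM(y, X, exog_vc, ident, vcp_p=2.0, fe_p=2.0)
    fit = model.fit_vb()

    params = np.asarray(fit.fe_mean)
    sd = np.asarray(fit.fe_sd)
    cov = np.diag(sd**2)
    tau00 = float(np.exp(2 * fit.vcp_mean[0]))
    sigma2 = float(np.pi**2 / 3)
    warns = []
    if np.any(np.abs(params) > 10):
        warns.append("possible complete separation: extreme fixed-effect estimates")
    zvals = params / sd
    pvals = 2 * stats.norm.sf(np.abs(zvals))
    r2m, r2c = _r_squared(X, params, tau00, sigma2)
    table = pd.DataFrame(
        {
            "term": names,
            "odds_ratio": np.exp(params),
            "or_ci_low": np.exp(params - 1.96 * sd),
            "or_ci_high": np.exp(params + 1.96 * sd),
            "estimate": params,
            "z": zvals,
            "p": pvals,
        }
    )
    table.attrs["random_effects"] = {
        "sigma2": sigma2,
        "tau00": tau00,
        "icc": tau00 / (tau00 + sigma2),
        "n_obs": len(y),
        "n_groups": int(n_groups),
        "r2_marginal": r2m,
        "r2_conditional": r2c,
    }
    return FittedModel(
        spec=spec,
        params=params,
        cov=cov,
        names=names,
        levels=levels,
        sigma2=sigma2,
        tau00=tau00,
        n_obs=len(y),
        n_groups=int(n_groups),
        df_map=np.full(len(params), np.inf),
        warnings=warns,
        summary_table=table,
    )


@dataclass
class ContrastResult:
    """One pairwise EMM contrast with its family-wise adjusted p-value."""

    label: str
    estimate: float
    se: float
    df: float
    stat: float
    p_unadjusted: float
    p_adjusted: float
    effect_size: Optional[float] = None


def _emm_rows(model: FittedModel, grid: pd.DataFrame) -> np.ndarray:
    """Design rows for a reference grid, averaging over unlisted factors."""
    spec, levels = model.spec, model.levels
    rows = np.zeros((len(grid), len(model.params)))
    others = [f for f in spec.factors if f not in grid.columns]
    combos = list(itertools.product(*[levels[f] for f in others])) or [()]
    for r, (_, cell) in enumerate(grid.iterrows()):
        for combo in combos:
            point = dict(cell)
            point.update(dict(zip(others, combo)))
            frame = pd.DataFrame([point])
            X, _ = _design_matrix(frame, spec, levels)
            rows[r] += X[0]
        rows[r] /= len(combos)
    return rows


def estimated_marginal_means(model: FittedModel, factors: Sequence[str]):
    """EMMs over the grid of the named factors, averaging the others with
    equal cell weights."""
    for f in factors:
        if f not in model.spec.factors:
            raise ValueError(f"factor {f!r} not in the model")
    grid = pd.DataFrame(
        list(itertools.product(*[model.levels[f] for f in factors])),
        columns=list(factors),
    )
    L = _emm_rows(model, grid)
    grid = grid.copy()
    grid["emmean"] = L @ model.params
    grid["se"] = np.sqrt(np.einsum("ij,jk,ik->i", L, model.cov, L))
    grid.attrs["L"] = L
    return grid


def emm_contrasts(
    model: FittedModel,
    factors: Sequence[str],
    by: Optional[Sequence[str]] = None,
    adjustment: str = "tukey",
) -> list:
    """Pairwise comparisons of estimated marginal means.

    ``factors`` defines the means being compared; ``by`` optionally slices
    the family (comparisons run within each slice, and the adjustment family
    is the slice). With a family of one comparison the Tukey adjustment
    leaves p unchanged.
    """
    if adjustment not in ("tukey", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    by = list(by or [])
    all_factors = by + [f for f in factors if f not in by]
    emms = estimated_marginal_means(model, all_factors)
    L = emms.attrs["L"]
    slices = emms.groupby(by) if by else [((), emms)]
    results = []
    for slice_key, block in slices:
        idx = block.index.to_numpy()
        k = len(idx)
        n_comp = k * (k - 1) // 2
        for i, j in itertools.combinations(range(k), 2):
            li, lj = L[idx[i]], L[idx[j]]
            diff = li - lj
            est = float(diff @ model.params)
            se = float(np.sqrt(diff @ model.cov @ diff))
            df = model.df_for(diff)
            stat = est / se
            if np.isfinite(df):
                p_un = 2 * stats.t.sf(abs(stat), df)
            else:
                p_un = 2 * stats.norm.sf(abs(stat))
            if adjustment == "tukey" and n_comp > 1:
                df_sr = df if np.isfinite(df) else 1e7
                p_adj = float(
                    stats.studentized_range.sf(abs(stat) * np.sqrt(2), k, df_sr)
                )
            else:
                p_adj = p_un
            p_adj = min(max(p_adj, p_un), 1.0)  # adjusted p never below unadjusted
            lab_i = ",".join(str(block.iloc[i][f]) for f in factors)
            lab_j = ",".join(str(block.iloc[j][f]) for f in factors)
            prefix = ""
            if by:
                key = slice_key if isinstance(slice_key, tuple) else (slice_key,)
                prefix = " ".join(f"{f}={v}" for f, v in zip(by, key)) + " | "
            results.append(
                ContrastResult(
                    label=f"{prefix}{lab_i} - {lab_j}",
                    estimate=est,
                    se=se,
                    df=df,
                    stat=stat,
                    p_unadjusted=float(p_un),
                    p_adjusted=float(p_adj),
                    effect_size=effect_size_value(est, model),
                )
            )
    return results


def effect_size_value(estimate: float, model: FittedModel) -> float:
    """Cohen's d standardized by the total random SD."""
    total_var = model.tau00 + model.sigma2
    if total_var <= 0:
        raise ValueError("zero total random variance; d is undefined")
    return estimate / float(np.sqrt(total_var))


def effect_size(contrast: ContrastResult, model: FittedModel) -> float:
    return effect_size_value(contrast.estimate, model)


def plot_emm_figures(models: dict, out_dir) -> list:
    """Estimated-marginal-mean bar charts, one figure per fitted model.

    ``models`` maps a name to (FittedModel, x_factor, hue_factor). Returns
    the written paths. Uses the non-interactive Agg backend.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, (model, x_factor, hue_factor) in models.items():
        emms = estimated_marginal_means(model, [x_factor, hue_factor])
        fig, ax = plt.subplots(figsize=(5, 3.5))
        hue_levels = model.levels[hue_factor]
        x_levels = model.levels[x_factor]
        width = 0.8 / len(hue_levels)
        xs = np.arange(len(x_levels))
        for j, hue in enumerate(hue_levels):
            block = emms[emms[hue_factor] == hue].set_index(x_factor)
            vals = block.loc[x_levels, "emmean"]
            errs = block.loc[x_levels, "se"]
            ax.bar(xs + j * width, vals, width, yerr=errs, capsize=3, label=hue)
        ax.set_xticks(xs + width * (len(hue_levels) - 1) / 2)
        ax.set_xticklabels(x_levels)
        ax.set_xlabel(x_factor)
        ax.set_ylabel(f"EMM of {model.spec.response}")
        ax.legend(title=hue_factor, fontsize=8)
        fig.tight_layout()
        path = out_dir / f"{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def _format_table(df: pd.DataFrame) -> str:
    re_block = df.attrs.get("random_effects", {})
    out = df.to_string(index=False, float_format=lambda v: f"{v:.4g}")
    if re_block:
        out += "\n\nRandom effects: " + ", ".join(
            f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
            for k, v in re_block.items()
        )
    return out


def report(outputs: dict, path, seed=None, config_text: str = "") -> str:
    """Assemble a plain-text report of all available stage outputs.

    ``outputs`` may hold any of: ``learning_rate_model``, ``accuracy_model``,
    ``weight_models`` (dict scheme -> FittedModel), ``loo_table``,
    ``contrasts`` (dict name -> list of ContrastResult). Missing stages are
    flagged explicitly rather than silently skipped.
    """
    from pathlib import Path

    lines = ["# Social reinforcement-learning analysis report", ""]
    if seed is not None:
        lines.append(f"seed: {seed}")
    if config_text:
        lines.extend(["", "## Configuration", "", config_text.strip(), ""])

    sections = [
        ("learning_rate_model", "Learning rates (training phase)"),
        ("accuracy_model", "Test-phase accuracy (trial-level GLMM)"),
        ("weight_models", "Speech update weights"),
        ("loo_table", "Model comparison (LOOIC)"),
        ("contrasts", "Pairwise EMM contrasts (Tukey-adjusted)"),
    ]
    for key, title in sections:
        lines.extend(["", f"## {title}", ""])
        obj = outputs.get(key)
        if obj is None:
            lines.append(f"[missing stage: {key}]")
            continue
        if key == "weight_models":
            for scheme, m in obj.items():
                lines.extend([f"### scheme: {scheme}", _format_table(m.summary_table), ""])
        elif key == "contrasts":
            for name, contrasts in obj.items():
                lines.append(f"### {name}")
                for c in contrasts:
                    lines.append(
                        f"  {c.label}: est={c.estimate:.4g} se={c.se:.4g} "
                        f"t({c.df:.1f})={c.stat:.2f} p={c.p_adjusted:.3g} "
                        f"d={c.effect_size:.2f}"
                    )
                lines.append("")
        elif isinstance(obj, FittedModel):
            lines.append(_format_table(obj.summary_table))
            for w in obj.warnings:
                lines.append(f"warning: {w}")
        elif isinstance(obj, pd.DataFrame):
            lines.append(obj.to_string(index=False))
        else:
            lines.append(str(obj))
    text = "\n".join(lines) + "\n"
    Path(path).write_text(text)
    return text
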