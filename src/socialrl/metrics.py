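"""Test-phase accuracy and speech update-weight estimation.

Accuracy is defined over the recombined test phase: *choose-reward* trials
pair the most rewarding face (p80) with an intermediate face (p70, p60, p40,
p30); *avoid-punish* trials pair the most punishing face (p20) with an
intermediate face. The p80-vs-p20 pair and intermediate-only pairs belong to
neither metric and are excluded. A trial is correct when the face with the
higher reward probability was chosen.

An update weight is the single-shot analogue of a learning rate, estimated
from one pre-rating -> feedback -> post-rating triplet:

    w = (post - pre) / (feedback - pre)

and aggregated per subject under one of four schemes: a single weight over
all 20 items, by prediction-error valence, by item valence, or all four
PE x item-valence cells. For poor-performance items the PE sign convention
reverses (feedback below the pre-rating is a *positive* error). Items with
zero prediction error leave the ratio undefined and are excluded with the
reason recorded. Weights are deliberately not clipped: overshooting (w > 1)
and counter-updating (w < 0) are real behaviors that the influence-based
outlier screen is there to catch, not hide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    ChoiceTrial,
    FACE_PROBS,
    ItemValence,
    Phase,
    SpeechItem,
    ValidationError,
)

__all__ = [
    "TrialLabel",
    "TestTrialLabel",
    "label_test_trial",
    "accuracy_table",
    "classify_pe",
    "item_weight",
    "UndefinedWeightError",
    "aggregate_weights",
    "UpdateWeightSet",
    "weights_table",
    "screen_outliers",
]

INTERMEDIATE_FACES = frozenset({"p70", "p60", "p40", "p30"})

SCHEMES = ("one", "pe_valence", "item_valence", "four")


class TrialLabel(str, Enum):
    CHOOSE_REWARD = "choose_reward"
    AVOID_PUNISH = "avoid_punish"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class TestTrialLabel:
    trial: ChoiceTrial
    label: TrialLabel
    correct: Optional[bool]


def label_test_trial(trial: ChoiceTrial) -> TestTrialLabel:
    """Classify a test trial as choose-reward, avoid-punish, or excluded."""
    if trial.phase is not Phase.TEST:
        raise ValidationError("accuracy labels are defined over test-phase trials")
    faces = set(trial.pair.faces)
    has_mid = bool(faces & INTERMEDIATE_FACES)
    if "p80" in faces and has_mid and "p20" not in faces:
        label = TrialLabel.CHOOSE_REWARD
    elif "p20" in faces and has_mid and "p80" not in faces:
        label = TrialLabel.AVOID_PUNISH
    else:
        label = TrialLabel.EXCLUDED
    if label is TrialLabel.EXCLUDED:
        return TestTrialLabel(trial, label, None)
    better = max(trial.pair.faces, key=lambda f: FACE_PROBS[f])
    return TestTrialLabel(trial, label, trial.chosen == better)


def accuracy_table(trials: Sequence[ChoiceTrial], conditions=None):
    """Per subject x session x trial-type accuracy.

    Returns (proportions, trial_records): proportions has one row per
    subject-session-label cell (cells with no eligible trials are flagged
    missing), and trial_records keeps each eligible trial as a Bernoulli
    observation for the trial-level GLMM.
    """
    conditions = conditions or {}
    records = []
    for t in trials:
        if t.phase is not Phase.TEST:
            continue
        lab = label_test_trial(t)
        if lab.label is TrialLabel.EXCLUDED:
            continue
        cond = conditions.get(t.subject_id, "")
        records.append(
            {
                "subject_id": t.subject_id,
                "condition": getattr(cond, "value", cond),
                "session": t.session,
                "trial_type": lab.label.value,
                "trial_index": t.trial_index,
                "correct": int(lab.correct),
            }
        )
    trial_records = pd.DataFrame(
        records,
        columns=[
            "subject_id", "condition", "session", "trial_type", "trial_index",
            "correct",
        ],
    )
    if trial_records.empty:
        return trial_records.copy(), trial_records

    cells = []
    grouped = trial_records.groupby(["subject_id", "session"])
    for (sid, session), block in grouped:
        for label in (TrialLabel.CHOOSE_REWARD, TrialLabel.AVOID_PUNISH):
            sub = block[block.trial_type == label.value]
            cells.append(
                {
                    "subject_id": sid,
                    "condition": block.condition.iloc[0],
                    "session": session,
                    "trial_type": label.value,
                    "n_trials": len(sub),
                    "accuracy": sub.correct.mean() if len(sub) else np.nan,
                    "missing": len(sub) == 0,
                }
            )
    return pd.DataFrame(cells), trial_records


def classify_pe(item: SpeechItem) -> str:
    """Sign of the feedback prediction error, respecting item valence.

    For good-performance items, feedback above the pre-rating is a positive
    error; for poor-performance items the convention reverses.
    """
    raw = item.feedback_rating - item.pre_rating
    if raw == 0:
        return "zero"
    signed = raw if item.valence is ItemValence.GOOD else -raw
    return "positive" if signed > 0 else "negative"


class UndefinedWeightError(ValueError):
    """Zero prediction error: the update-weight ratio is undefined."""


def item_weight(item: SpeechItem) -> float:
    """Single-item update weight (post - pre) / (feedback - pre)."""
    denom = item.feedback_rating - item.pre_rating
    if denom == 0:
        raise UndefinedWeightError(
            f"item {item.item_id} of {item.subject_id}: feedback equals the "
            "pre-rating, so the update weight is undefined"
        )
    return (item.post_rating - item.pre_rating) / denom


def _category(item: SpeechItem, scheme: str) -> str:
    if scheme == "one":
        return "all"
    pe = classify_pe(item)
    if scheme == "pe_valence":
        return pe
    if scheme == "item_valence":
        return item.valence.value
    if scheme == "four":
        return f"{pe}_{item.valence.value}"
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def _scheme_categories(scheme: str) -> tuple:
    return {
        "one": ("all",),
        "pe_valence": ("positive", "negative"),
        "item_valence": ("good", "poor"),
        "four": (
            "positive_good", "positive_poor", "negative_good", "negative_poor",
        ),
    }[scheme]


@dataclass
class UpdateWeightSet:
    """One subject's per-category mean update weights under a scheme.

    Categories with no retained items are flagged in ``missing`` rather than
    silently dropped; excluded items carry the reason.
    """

    subject_id: str
    scheme: str
    weights: dict = field(default_factory=dict)
    n_items: dict = field(default_factory=dict)
    excluded_items: list = field(default_factory=list)
    missing: list = field(default_factory=list)


def aggregate_weights(items: Sequence[SpeechItem], scheme: str) -> UpdateWeightSet:
    """Per-category arithmetic mean of item weights for one subject."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if not items:
        raise ValidationError("no speech items supplied")
    sid = items[0].subject_id
    per_cat: dict = {c: [] for c in _scheme_categories(scheme)}
    result = UpdateWeightSet(subject_id=sid, scheme=scheme)
    for item in items:
        if item.subject_id != sid:
            raise ValidationError("aggregate_weights operates on one subject")
        if classify_pe(item) == "zero":
            result.excluded_items.append(
                {"item_id": item.item_id, "reason": "zero prediction error"}
            )
            continue
        per_cat[_category(item, scheme)].append(item_weight(item))
    for cat, ws in per_cat.items():
        if ws:
            result.weights[cat] = float(np.mean(ws))
            result.n_items[cat] = len(ws)
        else:
            result.missing.append(cat)
    return result


def weights_table(items: Sequence[SpeechItem], scheme: str, conditions=None):
    """Long-format weight table across subjects (one row per category)."""
    conditions = conditions or {}
    by_subject: dict = {}
    for item in items:
        by_subject.setdefault(item.subject_id, []).append(item)
    rows = []
    for sid in sorted(by_subject):
        ws = aggregate_weights(by_subject[sid], scheme)
        cond = conditions.get(sid, "")
        for cat, w in ws.weights.items():
            rows.append(
                {
                    "subject_id": sid,
                    "condition": getattr(cond, "value", cond),
                    "category": cat,
                    "weight": w,
                    "n_items": ws.n_items[cat],
                }
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "condition", "category", "weight", "n_items"]
    )


def _gls_pieces(X, y, groups, sigma2, tau):
    """Per-group X'V^-1 X and X'V^-1 y for a random-intercept covariance,
    via the Sherman-Morrison closed form."""
    A = np.zeros((X.shape[1], X.shape[1]))
    b = np.zeros(X.shape[1])
    for g in np.unique(groups):
        m = groups == g
        Xg, yg = X[m], y[m]
        ng = m.sum()
        shrink = tau / (sigma2 + ng * tau)
        sx = Xg.sum(axis=0)
        sy = yg.sum()
        A += (Xg.T @ Xg - shrink * np.outer(sx, sx)) / sigma2
        b += (Xg.T @ yg - shrink * sx * sy) / sigma2
    return A, b


def screen_outliers(
    table: pd.DataFrame,
    spec=None,
    threshold: Optional[float] = None,
):
    """Influence-based outlier screening on a subject x category weight table.

    Fits the specified mixed model (default: weight ~ condition x category
    with a participant random intercept), then measures each observation's
    case-deletion influence on the fixed effects with the variance
    components held at the full-data fit — a Cook's-distance analogue

        D_i = (beta - beta_(-i))' (X' V^-1 X) (beta - beta_(-i)) / p

    Observations with D_i above the threshold (default 4/n) are removed in a
    single pass. Returns (retained, removed) where ``removed`` carries the
    influence scores.
    """
    from .inference import ModelSpec, _design_matrix, fit_lmm

    if spec is None:
        factors = ["category"]
        if table["condition"].nunique() > 1:
            factors = ["condition", "category"]
        spec = ModelSpec(response="weight", factors=tuple(factors))
    n = len(table)
    if threshold is None:
        threshold = 4.0 / n
    if n == 0 or not np.isfinite(threshold):
        return table.copy(), table.iloc[0:0].assign(influence=[])

    model = fit_lmm(table, spec)
    X, _ = _design_matrix(table.reset_index(drop=True), spec, model.levels)
    y = table[spec.response].astype(float).values
    groups = table[spec.group].astype(str).values
    sigma2, tau = model.sigma2, model.tau00
    p = X.shape[1]

    A, b = _gls_pieces(X, y, groups, sigma2, tau)
    beta = np.linalg.solve(A, b)
    influence = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Ai, bi = _gls_pieces(X[keep], y[keep], groups[keep], sigma2, tau)
        try:
            beta_i = np.linalg.solve(Ai, bi)
        except np.linalg.LinAlgError:
            influence[i] = np.inf
            continue
        d = beta - beta_i
        influence[i] = float(d @ A @ d) / p

    flagged = influence > threshold
    removed = table.loc[flagged].copy()
    removed["influence"] = influence[flagged]
    retained = table.loc[~flagged].copy()
    return retained, removed
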