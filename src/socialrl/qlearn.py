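"""Q-learning model of the selection task's training phase.

The agent carries an expected value q(face) in [0, 1] for each face
(initialized at 0.5, the indifference point, with outcomes coded
happy = 1, angry = 0). After each outcome the chosen face's value moves
toward the outcome by a learning rate chosen by the sign of the prediction
error delta = outcome - q:

    q' = q + alpha * delta,   alpha = alpha_reward if delta > 0
                                      else alpha_punish

Choices follow a softmax (logistic, for two options) in the current values:

    P(choose a over b) = 1 / (1 + exp(-beta * (q_a - q_b)))

The single-learning-rate model is the nested constraint
alpha_reward == alpha_punish; at any such parameter point the two models'
likelihoods agree exactly, which the test suite checks.

A zero prediction error is unreachable when q is strictly inside (0, 1) and
outcomes are {0, 1}; at the boundary (q exactly 0 or 1) the convention is
alpha_reward for outcome 1 and alpha_punish for outcome 0, where the update
is zero regardless.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .types import ChoiceTrial, FACE_IDS, Phase, QParameters, QState, ValidationError

__all__ = ["q_update", "choice_prob", "nll", "encode_trials", "nll_arrays"]

_FACE_INDEX = {f: i for i, f in enumerate(FACE_IDS)}


def q_update(q_chosen: float, outcome: int, params: QParameters) -> float:
    """One value update for the chosen face; unchosen faces are untouched."""
    delta = outcome - q_chosen
    if delta > 0:
        alpha = params.alpha_reward
    elif delta < 0:
        alpha = params.alpha_punish
    else:
        alpha = params.alpha_reward if outcome == 1 else params.alpha_punish
    return q_chosen + alpha * delta


def choice_prob(q_a: float, q_b: float, beta: float) -> float:
    """Softmax probability of choosing face a over face b."""
    if beta < 0:
        raise ValidationError(f"beta={beta} must be >= 0")
    # expit, written out to keep this hot path free of scipy dispatch
    x = beta * (q_a - q_b)
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    ex = np.exp(x)
    return ex / (1.0 + ex)


def encode_trials(trials: Sequence[ChoiceTrial]):
    """Pack one subject-session's training trials into integer arrays.

    Returns (chosen_idx, other_idx, outcome) with faces coded 0..5 in the
    canonical order. Raises on any non-training trial.
    """
    n = len(trials)
    chosen = np.empty(n, dtype=np.intp)
    other = np.empty(n, dtype=np.intp)
    outcome = np.empty(n, dtype=np.float64)
    for i, t in enumerate(trials):
        if t.phase is not Phase.TRAIN:
            raise ValidationError(
                f"trial {t.trial_index} of subject {t.subject_id} is not a "
                "training trial; the likelihood is defined over the training phase"
            )
        chosen[i] = _FACE_INDEX[t.chosen]
        a, b = t.pair.face_a, t.pair.face_b
        other[i] = _FACE_INDEX[b if t.chosen == a else a]
        outcome[i] = 1.0 if t.outcome.value == "happy" else 0.0
    return chosen, other, outcome


def nll_arrays(chosen, other, outcome, alpha_reward, alpha_punish, beta,
               q0: float = 0.5):
    """Negative log-likelihood on encoded arrays.

    Returns (total_nll, pointwise_loglik). The replay is inherently
    sequential, so this is a tight Python loop over scalars.
    """
    q = [q0] * len(FACE_IDS)
    n = len(chosen)
    pointwise = np.empty(n, dtype=np.float64)
    for i in range(n):
        c = chosen[i]
        dq = beta * (q[c] - q[other[i]])
        # log(sigmoid(dq)) computed stably
        if dq >= 0:
            ll = -np.log1p(np.exp(-dq))
        else:
            ll = dq - np.log1p(np.exp(dq))
        pointwise[i] = ll
        delta = outcome[i] - q[c]
        alpha = alpha_reward if delta > 0 else alpha_punish
        if delta == 0.0 and outcome[i] == 1.0:
            alpha = alpha_reward
        q[c] += alpha * delta
    return -float(pointwise.sum()), pointwise


def nll(trials: Sequence[ChoiceTrial], params: QParameters):
    """Negative log-likelihood of one subject-session's training choices.

    Returns (total_nll, pointwise_loglik) where ``pointwise_loglik`` has one
    entry per trial and sums (negated) to the total.
    """
    chosen, other, outcome = encode_trials(trials)
    return nll_arrays(
        chosen, other, outcome, params.alpha_reward, params.alpha_punish, params.beta
    )


def replay_q_values(trials: Sequence[ChoiceTrial], params: QParameters) -> QState:
    """Final expected values after replaying a training sequence."""
    state = QState()
    for t in trials:
        if t.phase is not Phase.TRAIN:
            raise ValidationError("can only replay training trials")
        out = 1 if t.outcome.value == "happy" else 0
        state[t.chosen] = q_update(state[t.chosen], out, params)
    return state
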