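"""Synthetic cohort generator.

Produces complete studies with known ground truth: subjects split across the
two arms, both sessions of the selection task played by Q-learning agents
with known parameters, and session-2 speech records generated from known
update weights. Every randomized operation takes an explicit seed; subject-
level substreams are spawned deterministically from the master seed so any
one subject can be regenerated in isolation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .config import CohortConfig, RunConfig, TaskConfig
from .qlearn import choice_prob, q_update
from .types import (
    ChoiceTrial,
    Condition,
    FACE_IDS,
    FacePair,
    ItemValence,
    Outcome,
    Phase,
    QParameters,
    QState,
    SpeechItem,
    StudyDesign,
    TRAINING_PAIRS,
    ValidationError,
)

__all__ = [
    "AgentSpec",
    "TaskSchedule",
    "make_design",
    "sample_outcome",
    "simulate_training",
    "simulate_testing",
    "feedback_value",
    "generate_feedback",
    "simulate_speech",
    "simulate_rate_table",
    "simulate_study",
]

#: Update-weight categories: (PE valence, item valence) cells.
WEIGHT_CELLS = (
    ("positive", "good"),
    ("positive", "poor"),
    ("negative", "good"),
    ("negative", "poor"),
)


@dataclass(frozen=True)
class AgentSpec:
    """Ground truth for one synthetic subject.

    ``q_params`` maps session -> generating Q-learning parameters;
    ``speech_weights`` maps (pe_valence, item_valence) -> the true update
    weight applied to the feedback prediction error; ``speech_noise_sd`` is
    Gaussian noise (rating points) added to post-ratings before clipping.
    """

    subject_id: str
    condition: Condition
    q_params: Mapping[int, QParameters]
    speech_weights: Mapping[tuple, float]
    speech_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for w in self.speech_weights.values():
            if not (0.0 <= w <= 1.0):
                raise ValidationError(f"true update weight {w} outside [0, 1]")
        if self.speech_noise_sd < 0:
            raise ValidationError("speech_noise_sd must be >= 0")


@dataclass(frozen=True)
class TaskSchedule:
    """Presentation counts: training restricted to the three complementary
    pairs; test phase covers the recombined pairs."""

    training_pairs: tuple = tuple(
        (FacePair.of(a, b), 80) for a, b in TRAINING_PAIRS
    )
    test_pairs: tuple = tuple(
        (FacePair.of(a, b), 4) for a, b in itertools.combinations(FACE_IDS, 2)
    )

    def __post_init__(self) -> None:
        for pair, _count in self.training_pairs:
            if not pair.is_training_pair():
                raise ValidationError(
                    f"{pair.faces} is not one of the complementary training pairs"
                )

    @classmethod
    def from_config(cls, task: TaskConfig) -> "TaskSchedule":
        per_pair = task.trials_per_pair_per_block * task.n_blocks
        return cls(
            training_pairs=tuple(
                (FacePair.of(a, b), per_pair) for a, b in TRAINING_PAIRS
            ),
            test_pairs=tuple(
                (FacePair.of(a, b), task.test_repetitions)
                for a, b in itertools.combinations(FACE_IDS, 2)
            ),
        )


def make_design(n_cbmi: int, n_ema: int, seed: int) -> list[StudyDesign]:
    """Assign ``n_cbmi + n_ema`` subjects to the two arms.

    Ids are zero-padded and the arm order is shuffled deterministically so
    condition is not confounded with id order.
    """
    if n_cbmi < 0 or n_ema < 0:
        raise ValidationError("subject counts must be >= 0")
    rng = np.random.default_rng(seed)
    arms = [Condition.CBMI] * n_cbmi + [Condition.EMA_ONLY] * n_ema
    rng.shuffle(arms)
    width = max(3, len(str(max(len(arms), 1))))
    return [
        StudyDesign(f"S{i + 1:0{width}d}", cond) for i, cond in enumerate(arms)
    ]


def sample_outcome(pair: FacePair, chosen: str, rng: np.random.Generator) -> Outcome:
    """Draw the face's reaction: happy with its reward probability, else angry."""
    p = pair.p_reward(chosen)
    return Outcome.HAPPY if rng.random() < p else Outcome.ANGRY


def _interleave_schedule(pairs_with_counts, rng) -> list[FacePair]:
    order = []
    for pair, count in pairs_with_counts:
        order.extend([pair] * count)
    rng.shuffle(order)
    return order


def simulate_training(
    subject_id: str,
    session: int,
    params: QParameters,
    schedule: TaskSchedule,
    rng: np.random.Generator,
) -> tuple[list[ChoiceTrial], QState]:
    """Play the training phase with a Q-learning agent.

    Returns the trials and the agent's final expected values (used to seed
    the frozen test phase). The schedule's pair presentations are shuffled
    into one interleaved sequence.
    """
    state = QState()
    trials = []
    order = _interleave_schedule(schedule.training_pairs, rng)
    for idx, pair in enumerate(order):
        p_a = choice_prob(state[pair.face_a], state[pair.face_b], params.beta)
        chosen = pair.face_a if rng.random() < p_a else pair.face_b
        outcome = sample_outcome(pair, chosen, rng)
        trials.append(
            ChoiceTrial(subject_id, session, Phase.TRAIN, idx, pair, chosen, outcome)
        )
        state[chosen] = q_update(
            state[chosen], 1 if outcome is Outcome.HAPPY else 0, params
        )
    return trials, state


def simulate_testing(
    subject_id: str,
    session: int,
    q_values: QState,
    beta: float,
    schedule: TaskSchedule,
    rng: np.random.Generator,
) -> list[ChoiceTrial]:
    """Play the no-feedback test phase with frozen values."""
    for face in FACE_IDS:
        q_values[face]  # raises on a missing face value
    trials = []
    order = _interleave_schedule(schedule.test_pairs, rng)
    for idx, pair in enumerate(order):
        p_a = choice_prob(q_values[pair.face_a], q_values[pair.face_b], beta)
        chosen = pair.face_a if rng.random() < p_a else pair.face_b
        trials.append(
            ChoiceTrial(
                subject_id, session, Phase.TEST, idx, pair, chosen, Outcome.NONE
            )
        )
    return trials


def feedback_value(pre_rating: int, offset: int) -> int:
    """Deterministic core of the false-feedback rule: clip(pre + offset) to
    the 0-100 rating scale. Exposed so the rule can be checked exhaustively
    over all (pre, offset) combinations."""
    if not 0 <= pre_rating <= 100:
        raise ValidationError(f"pre_rating={pre_rating} outside [0, 100]")
    if not -50 <= offset <= 50:
        raise ValidationError(f"offset={offset} outside [-50, 50]")
    return int(np.clip(pre_rating + offset, 0, 100))


def generate_feedback(pre_rating: int, rng: np.random.Generator) -> int:
    """False judge feedback: pre-rating plus a uniform integer offset in
    [-50, 50], clipped to the 0-100 rating scale."""
    return feedback_value(pre_rating, int(rng.integers(-50, 51)))


def simulate_speech(
    agent: AgentSpec,
    pre_ratings: Sequence[int],
    rng: np.random.Generator,
) -> list[SpeechItem]:
    """Generate the 20 speech items (10 good then 10 poor) for one subject.

    post = pre + w_true(cell) * (feedback - pre) + noise, clipped to [0, 100].
    The cell is the (PE valence, item valence) combination implied by the
    drawn feedback; noise is applied before clipping.
    """
    if len(pre_ratings) != 20:
        raise ValidationError("exactly 20 pre-ratings required (10 good, 10 poor)")
    items = []
    for item_id, pre in enumerate(pre_ratings, start=1):
        valence = ItemValence.GOOD if item_id <= 10 else ItemValence.POOR
        feedback = generate_feedback(int(pre), rng)
        # PE sign convention: for poor-performance items higher feedback is worse
        raw = feedback - pre
        signed = raw if valence is ItemValence.GOOD else -raw
        pe_val = "positive" if signed > 0 else "negative"
        w = agent.speech_weights[(pe_val, valence.value)]
        post = pre + w * raw
        if agent.speech_noise_sd > 0:
            post += rng.normal(0.0, agent.speech_noise_sd)
        post = float(np.clip(post, 0.0, 100.0))
        items.append(
            SpeechItem(agent.subject_id, item_id, valence, int(pre), feedback, post)
        )
    return items


def simulate_rate_table(
    n_per_arm: int,
    seed: int,
    grand_mean: float = 0.23,
    subject_sd: float = 0.04,
    resid_sd: float = 0.08,
    effects: Mapping[str, float] | None = None,
):
    """Generate a learning-rate table straight from the mixed-effects world.

    This is the scaled-down generator for calibration and power studies of
    the inference stage: one row per subject x session x PE-valence cell,
    rate = grand mean + effects-coded fixed effects + subject intercept +
    residual noise. ``effects`` maps term names (e.g. ``"session x
    condition"``) to coefficients on the effects-coded (+-1/2) scale, so a
    coefficient equals the difference-in-differences it induces. The default
    variance components (subject SD 0.04, residual SD 0.08) give an ICC of
    ~0.2, the scale seen in this paradigm's learning-rate tables.
    """
    import pandas as pd

    from .inference import ModelSpec, _design_matrix, _factor_levels

    rng = np.random.default_rng(seed)
    rows = []
    for i in range(2 * n_per_arm):
        cond = "CBM-I" if i < n_per_arm else "EMA-only"
        for session in ("1", "2"):
            for valence in ("negative", "positive"):
                rows.append(
                    {
                        "subject_id": f"S{i + 1:03d}",
                        "condition": cond,
                        "session": session,
                        "pe_valence": valence,
                    }
                )
    data = pd.DataFrame(rows)
    spec = ModelSpec("rate", ("session", "condition", "pe_valence"))
    levels = _factor_levels(data, spec.factors)
    X, names = _design_matrix(data, spec, levels)
    beta = np.zeros(X.shape[1])
    beta[0] = grand_mean
    for term, coef in (effects or {}).items():
        if term not in names:
            raise ValidationError(f"unknown effect term {term!r}; options: {names}")
        beta[names.index(term)] = coef
    intercepts = rng.normal(0.0, subject_sd, 2 * n_per_arm)
    subj_idx = np.repeat(np.arange(2 * n_per_arm), 4)
    data["rate"] = X @ beta + intercepts[subj_idx] + rng.normal(0, resid_sd, len(data))
    return data


def _draw_agent(
    design: StudyDesign, cohort: CohortConfig, rng: np.random.Generator
) -> AgentSpec:
    from scipy.special import expit

    a_r = float(expit(rng.normal(cohort.alpha_logit_mean, cohort.alpha_logit_sd)))
    a_p = float(expit(rng.normal(cohort.alpha_logit_mean, cohort.alpha_logit_sd)))
    beta = float(np.exp(rng.normal(cohort.beta_log_mean, cohort.beta_log_sd)))
    shift = 0.0
    if design.condition is Condition.CBMI:
        shift += cohort.cbmi_session2_alpha_shift
    pe_shift = cohort.session2_pe_valence_shift
    params = {
        1: QParameters(a_r, a_p, beta),
        2: QParameters(
            float(np.clip(a_r + shift + pe_shift / 2.0, 0.0, 1.0)),
            float(np.clip(a_p + shift - pe_shift / 2.0, 0.0, 1.0)),
            beta,
        ),
    }
    base = float(
        np.clip(rng.normal(cohort.speech_weight_mean, cohort.speech_weight_sd), 0, 1)
    )
    weights = {}
    for pe_val, item_val in WEIGHT_CELLS:
        w = base
        w += (0.5 if pe_val == "positive" else -0.5) * cohort.speech_pe_valence_effect
        w += (0.5 if item_val == "poor" else -0.5) * cohort.speech_item_valence_effect
        weights[(pe_val, item_val)] = float(np.clip(w, 0.0, 1.0))
    return AgentSpec(
        design.subject_id, design.condition, params, weights, cohort.speech_noise_sd
    )


@dataclass
class StudyTables:
    """The four mutually consistent outputs of one simulated study."""

    designs: list = field(default_factory=list)
    trials: list = field(default_factory=list)
    speech: list = field(default_factory=list)
    truth: dict = field(default_factory=dict)


def simulate_study(config: RunConfig, seed: int) -> StudyTables:
    """Simulate a full study: design, both selection-task sessions per
    subject, session-2 speech records, and the retained ground truth."""
    master = np.random.SeedSequence(seed)
    design_seed, agents_seed = master.spawn(2)
    designs = make_design(
        config.cohort.n_cbmi,
        config.cohort.n_ema,
        np.random.default_rng(design_seed).integers(2**31),
    )
    schedule = TaskSchedule.from_config(config.task)
    study = StudyTables(designs=designs)
    subject_streams = agents_seed.spawn(len(designs))
    for design, stream in zip(designs, subject_streams):
        rng = np.random.default_rng(stream)
        agent = _draw_agent(design, config.cohort, rng)
        truth_entry = {
            "condition": design.condition.value,
            "q_params": {
                str(s): {
                    "alpha_reward": p.alpha_reward,
                    "alpha_punish": p.alpha_punish,
                    "beta": p.beta,
                }
                for s, p in agent.q_params.items()
            },
            "speech_weights": {
                f"{pe}_{iv}": w for (pe, iv), w in agent.speech_weights.items()
            },
        }
        study.truth[design.subject_id] = truth_entry
        for session in sorted(design.sessions_present):
            train, state = simulate_training(
                design.subject_id, session, agent.q_params[session], schedule, rng
            )
            test = simulate_testing(
                design.subject_id,
                session,
                state,
                agent.q_params[session].beta,
                schedule,
                rng,
            )
            study.trials.extend(train)
            study.trials.extend(test)
        if 2 in design.sessions_present:
            pre = rng.integers(
                config.cohort.pre_rating_low, config.cohort.pre_rating_high + 1, 20
            )
            study.speech.extend(simulate_speech(agent, [int(x) for x in pre], rng))
    return study
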