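"""Core domain types for the social reinforcement-learning pipeline.

The study has two behavioral paradigms:

* a social probabilistic selection task, in which six neutral faces carry
  fixed reward probabilities (a chosen face becomes happy with that
  probability, angry otherwise) and participants learn by trial and error
  during a training phase before a no-feedback test phase over all
  recombined face pairs; and
* a speech-expectancies task, in which participants rate 20 statements about
  their own speech performance (10 describing good performance, 10 poor)
  before and after seeing item-wise feedback, on a 0-100 agree scale.

Faces are named by their reward probability ("p80" becomes happy 80% of the
time it is chosen), which makes trial tables self-describing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

__all__ = [
    "FACE_IDS",
    "FACE_PROBS",
    "TRAINING_PAIRS",
    "Condition",
    "Phase",
    "Outcome",
    "ItemValence",
    "StudyDesign",
    "FacePair",
    "ChoiceTrial",
    "SpeechItem",
    "QParameters",
    "QState",
    "ValidationError",
    "SchemaError",
]

#: The six faces, ordered from most to least rewarding.
FACE_IDS = ("p80", "p70", "p60", "p40", "p30", "p20")

#: Nominal probability that each face becomes happy when chosen.
FACE_PROBS: Mapping[str, float] = {
    "p80": 0.80,
    "p70": 0.70,
    "p60": 0.60,
    "p40": 0.40,
    "p30": 0.30,
    "p20": 0.20,
}

#: The three complementary training pairs (80/20, 70/30, 60/40).
TRAINING_PAIRS = (("p80", "p20"), ("p70", "p30"), ("p60", "p40"))


class ValidationError(ValueError):
    """A record violates a domain invariant (carries row context when known)."""


class SchemaError(ValueError):
    """A table is missing or mis-typing a required column."""


class Condition(str, Enum):
    """Intervention arm: interpretation-bias training plus EMA, or EMA only."""

    CBMI = "CBM-I"
    EMA_ONLY = "EMA-only"


class Phase(str, Enum):
    TRAIN = "train"
    TEST = "test"


class Outcome(str, Enum):
    HAPPY = "happy"
    ANGRY = "angry"
    NONE = "none"


class ItemValence(str, Enum):
    """Whether a speech item describes good or poor performance."""

    GOOD = "good"
    POOR = "poor"


@dataclass(frozen=True)
class StudyDesign:
    """One subject's assignment: condition and which sessions they completed."""

    subject_id: str
    condition: Condition
    sessions_present: frozenset = frozenset({1, 2})

    def __post_init__(self) -> None:
        if not isinstance(self.condition, Condition):
            object.__setattr__(self, "condition", Condition(self.condition))
        bad = set(self.sessions_present) - {1, 2}
        if bad:
            raise ValidationError(f"unknown sessions {sorted(bad)} for {self.subject_id}")


@dataclass(frozen=True)
class FacePair:
    """An unordered pair of faces with their reward probabilities."""

    face_a: str
    face_b: str
    p_reward_a: float
    p_reward_b: float

    def __post_init__(self) -> None:
        if self.face_a == self.face_b:
            raise ValidationError("pair must contain two distinct faces")
        for p in (self.p_reward_a, self.p_reward_b):
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"reward probability {p} outside [0, 1]")

    @classmethod
    def of(cls, face_a: str, face_b: str) -> "FacePair":
        """Build a pair from the canonical face ids, looking up probabilities."""
        try:
            return cls(face_a, face_b, FACE_PROBS[face_a], FACE_PROBS[face_b])
        except KeyError as exc:
            raise ValidationError(f"unknown face id {exc.args[0]!r}") from None

    @property
    def faces(self) -> tuple:
        return (self.face_a, self.face_b)

    def p_reward(self, face: str) -> float:
        if face == self.face_a:
            return self.p_reward_a
        if face == self.face_b:
            return self.p_reward_b
        raise ValidationError(f"face {face!r} not in pair {self.faces}")

    def is_training_pair(self) -> bool:
        key = frozenset(self.faces)
        return any(key == frozenset(tp) for tp in TRAINING_PAIRS)


@dataclass(frozen=True)
class ChoiceTrial:
    """One selection-task trial: the pair shown, the face chosen, the outcome.

    Test-phase trials carry outcome ``none`` — the faces stay neutral once
    feedback is withdrawn.
    """

    subject_id: str
    session: int
    phase: Phase
    trial_index: int
    pair: FacePair
    chosen: str
    outcome: Outcome

    def __post_init__(self) -> None:
        if not isinstance(self.phase, Phase):
            object.__setattr__(self, "phase", Phase(self.phase))
        if not isinstance(self.outcome, Outcome):
            object.__setattr__(self, "outcome", Outcome(self.outcome))
        if self.session not in (1, 2):
            raise ValidationError(f"session must be 1 or 2, got {self.session}")
        if self.trial_index < 0:
            raise ValidationError("trial_index must be >= 0")
        if self.chosen not in self.pair.faces:
            raise ValidationError(
                f"chosen face {self.chosen!r} not in pair {self.pair.faces}"
            )
        if (self.outcome is Outcome.NONE) != (self.phase is Phase.TEST):
            raise ValidationError(
                "outcome must be 'none' exactly on test-phase trials "
                f"(phase={self.phase.value}, outcome={self.outcome.value})"
            )


@dataclass(frozen=True)
class SpeechItem:
    """One expectancy item: pre-rating, (false) feedback, and post-rating."""

    subject_id: str
    item_id: int
    valence: ItemValence
    pre_rating: int
    feedback_rating: int
    post_rating: float

    def __post_init__(self) -> None:
        if not isinstance(self.valence, ItemValence):
            object.__setattr__(self, "valence", ItemValence(self.valence))
        if not 1 <= self.item_id <= 20:
            raise ValidationError(f"item_id must be in 1..20, got {self.item_id}")
        for name in ("pre_rating", "feedback_rating", "post_rating"):
            v = getattr(self, name)
            if not (0 <= v <= 100) or (isinstance(v, float) and math.isnan(v)):
                raise ValidationError(f"{name}={v} outside the 0-100 rating scale")


@dataclass(frozen=True)
class QParameters:
    """Q-learning agent parameters.

    ``alpha_reward`` and ``alpha_punish`` weight positive and negative
    prediction errors respectively; ``beta`` is the softmax inverse
    temperature (0 = random choice). The single-learning-rate model is the
    constraint ``alpha_reward == alpha_punish``.
    """

    alpha_reward: float
    alpha_punish: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("alpha_reward", "alpha_punish"):
            a = getattr(self, name)
            if not (0.0 <= a <= 1.0):
                raise ValidationError(f"{name}={a} outside [0, 1]")
        if self.beta < 0:
            raise ValidationError(f"beta={self.beta} must be >= 0")

    @classmethod
    def single(cls, alpha: float, beta: float) -> "QParameters":
        return cls(alpha, alpha, beta)

    @property
    def is_single_rate(self) -> bool:
        return self.alpha_reward == self.alpha_punish


@dataclass
class QState:
    """Per-face expected values, initialized at the indifference point 0.5."""

    q: dict = field(default_factory=lambda: {f: 0.5 for f in FACE_IDS})

    def __getitem__(self, face: str) -> float:
        try:
            return self.q[face]
        except KeyError:
            raise ValidationError(f"no expected value for face {face!r}") from None

    def __setitem__(self, face: str, value: float) -> None:
        self.q[face] = value
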