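"""Tabular readers and writers for trial, speech, and design tables.

All tables are comma-delimited UTF-8 with fixed headers; rows are validated
against the domain invariants on read, and malformed rows are rejected with
the offending row number rather than coerced.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    ChoiceTrial,
    Condition,
    FacePair,
    ItemValence,
    Outcome,
    Phase,
    SchemaError,
    SpeechItem,
    StudyDesign,
    ValidationError,
)

TRIAL_COLUMNS = [
    "subject_id",
    "condition",
    "session",
    "phase",
    "trial_index",
    "face_a",
    "face_b",
    "chosen",
    "outcome",
]

SPEECH_COLUMNS = [
    "subject_id",
    "condition",
    "item_id",
    "valence",
    "pre_rating",
    "feedback_rating",
    "post_rating",
]

DESIGN_COLUMNS = ["subject_id", "condition", "sessions_present"]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def read_trials(path) -> list[ChoiceTrial]:
    """Read a trial table, validating every row.

    Raises :class:`SchemaError` for a missing column and
    :class:`ValidationError` (naming the 1-based data row) for an invariant
    violation. Row order is preserved.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, TRIAL_COLUMNS, "trial")
    trials = []
    seen_index: dict = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            session = int(row.session)
            trial_index = int(row.trial_index)
            pair = FacePair.of(row.face_a, row.face_b)
            trial = ChoiceTrial(
                subject_id=row.subject_id,
                session=session,
                phase=Phase(row.phase),
                trial_index=trial_index,
                pair=pair,
                chosen=row.chosen,
                outcome=Outcome(row.outcome),
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"trial table row {i}: {exc}") from None
        key = (trial.subject_id, trial.session, trial.phase)
        prev = seen_index.get(key)
        if prev is not None and trial.trial_index <= prev:
            raise ValidationError(
                f"trial table row {i}: trial_index {trial.trial_index} not strictly "
                f"increasing within subject {trial.subject_id} session {session} "
                f"phase {trial.phase.value}"
            )
        seen_index[key] = trial.trial_index
        trials.append(trial)
    return trials


def write_trials(trials: Iterable[ChoiceTrial], path, conditions=None) -> Path:
    """Write trials as CSV; ``conditions`` maps subject_id -> Condition.

    When ``conditions`` is omitted the condition column is left empty, which
    still round-trips (the column is informational on the trial table).
    """
    conditions = conditions or {}
    rows = []
    for t in trials:
        cond = conditions.get(t.subject_id, "")
        rows.append(
            {
                "subject_id": t.subject_id,
                "condition": cond.value if isinstance(cond, Condition) else cond,
                "session": t.session,
                "phase": t.phase.value,
                "trial_index": t.trial_index,
                "face_a": t.pair.face_a,
                "face_b": t.pair.face_b,
                "chosen": t.chosen,
                "outcome": t.outcome.value,
            }
        )
    path = Path(path)
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)
    return path


def read_speech(path) -> list[SpeechItem]:
    """Read a speech-expectancy item table, validating each row and the
    10-good / 10-poor composition per subject."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, SPEECH_COLUMNS, "speech")
    items = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            item = SpeechItem(
                subject_id=row.subject_id,
                item_id=int(row.item_id),
                valence=ItemValence(row.valence),
                pre_rating=int(row.pre_rating),
                feedback_rating=int(row.feedback_rating),
                post_rating=float(row.post_rating),
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"speech table row {i}: {exc}") from None
        items.append(item)
    counts: dict = {}
    for item in items:
        c = counts.setdefault(item.subject_id, {"good": 0, "poor": 0})
        c[item.valence.value] += 1
    for sid, c in counts.items():
        if c["good"] != 10 or c["poor"] != 10:
            raise ValidationError(
                f"subject {sid}: expected 10 good and 10 poor items, "
                f"got {c['good']} good and {c['poor']} poor"
            )
    return items


def write_speech(items: Iterable[SpeechItem], path, conditions=None) -> Path:
    conditions = conditions or {}
    rows = []
    for it in items:
        cond = conditions.get(it.subject_id, "")
        rows.append(
            {
                "subject_id": it.subject_id,
                "condition": cond.value if isinstance(cond, Condition) else cond,
                "item_id": it.item_id,
                "valence": it.valence.value,
                "pre_rating": it.pre_rating,
                "feedback_rating": it.feedback_rating,
                "post_rating": it.post_rating,
            }
        )
    path = Path(path)
    pd.DataFrame(rows, columns=SPEECH_COLUMNS).to_csv(path, index=False)
    return path


def read_design(path) -> list[StudyDesign]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, DESIGN_COLUMNS, "design")
    designs = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            sessions = frozenset(int(s) for s in row.sessions_present.split("|"))
            designs.append(
                StudyDesign(row.subject_id, Condition(row.condition), sessions)
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"design table row {i}: {exc}") from None
    return designs


def write_design(designs: Iterable[StudyDesign], path) -> Path:
    rows = [
        {
            "subject_id": d.subject_id,
            "condition": d.condition.value,
            "sessions_present": "|".join(str(s) for s in sorted(d.sessions_present)),
        }
        for d in designs
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=DESIGN_COLUMNS).to_csv(path, index=False)
    return path


def condition_map(designs: Iterable[StudyDesign]) -> dict:
    return {d.subject_id: d.condition for d in designs}


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
    return path


def read_json(path):
    return json.loads(Path(path).read_text())
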