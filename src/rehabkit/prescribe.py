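"""Exercise catalog, difficulty initialization and once-daily prescription adaptation.

The training program consists of 16 exercises for coordinated movement of the
upper extremity (8), hand (5) and lower extremity (3).  The starting difficulty
is derived from the patient's Fugl-Meyer total score at enrollment; afterwards
the difficulty adapts at most once per calendar day based on the change in the
session score, with a dead band of 5 points.
"""
from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from importlib import resources

from .difficulty import DIFFICULTY_ORDER, DifficultyLevel

#: Device roles required per body segment.
SEGMENT_DEVICES: dict[str, frozenset[str]] = {
    "upper": frozenset({"upper_arm", "lower_arm"}),
    "hand": frozenset({"glove"}),
    "lower": frozenset({"thigh", "calf"}),
}


class CatalogError(KeyError):
    """Raised when an exercise id is not in the catalog."""


@dataclass(frozen=True)
class ExerciseSpec:
    """One catalog entry: which body segment it trains and which devices it needs."""

    id: str
    name: str
    segment: str  # upper | hand | lower

    @property
    def required_devices(self) -> frozenset[str]:
        return SEGMENT_DEVICES[self.segment]

    @property
    def uses_glove(self) -> bool:
        return "glove" in self.required_devices


def _load_catalog() -> dict[str, ExerciseSpec]:
    raw = json.loads(
        resources.files("rehabkit.data").joinpath("exercises.json").read_text()
    )
    catalog = {}
    for entry in raw["exercises"]:
        spec = ExerciseSpec(id=entry["id"], name=entry["name"], segment=entry["segment"])
        catalog[spec.id] = spec
    return catalog


_CATALOG: dict[str, ExerciseSpec] = _load_catalog()


def list_exercises(segment: str | None = None) -> list[ExerciseSpec]:
    """All catalog entries, optionally restricted to one body segment."""
    specs = list(_CATALOG.values())
    if segment is not None:
        specs = [s for s in specs if s.segment == segment]
    return specs


def get_exercise(exercise_id: str) -> ExerciseSpec:
    try:
        return _CATALOG[exercise_id]
    except KeyError:
        raise CatalogError(f"unknown exercise id: {exercise_id!r}") from None


#: FMA-total bands mapping enrollment score to starting difficulty.
#: The clinical protocol ties starting difficulty to the enrollment FMA score
#: without printing cut points; thirds of the 0-100 scale are the default.
DEFAULT_FMA_BANDS: tuple[tuple[int, str], ...] = (
    (33, "easy"),
    (66, "moderate"),
    (100, "hard"),
)


def initial_difficulty(
    fma_total: float,
    bands: tuple[tuple[int, str], ...] = DEFAULT_FMA_BANDS,
) -> DifficultyLevel:
    """Map an enrollment FMA total (0-100) to the starting difficulty level."""
    if not 0 <= fma_total <= 100:
        raise ValueError(f"FMA total must be in [0, 100], got {fma_total}")
    for upper, level in bands:
        if fma_total <= upper:
            return DifficultyLevel.from_name(level)
    return DifficultyLevel.from_name(bands[-1][1])


@dataclass(frozen=True)
class PrescriptionItem:
    """One prescribed exercise: difficulty, repetition target and session length."""

    exercise_id: str
    difficulty: str
    target_reps: int = 10
    session_minutes: int = 30
    sessions_per_day: int = 2

    def to_dict(self) -> dict:
        return {
            "exercise_id": self.exercise_id,
            "difficulty": self.difficulty,
            "target_reps": self.target_reps,
            "session_minutes": self.session_minutes,
            "sessions_per_day": self.sessions_per_day,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PrescriptionItem":
        return cls(**d)


@dataclass(frozen=True)
class AdaptationState:
    """Bookkeeping for the once-per-day difficulty adaptation rule."""

    last_adjust_date: _dt.date | None = None
    last_session_score: float = 0.0


#: Session-score change (0-100 scale) that must be exceeded to trigger a step.
ADAPT_DEAD_BAND = 5.0


def adapt(
    state: AdaptationState,
    new_score: float,
    current: DifficultyLevel,
    today: _dt.date,
) -> tuple[DifficultyLevel, AdaptationState]:
    """Apply the once-daily adaptation rule.

    At most one adjustment happens per calendar date.  A session-score change
    of 5 points or less (in absolute value) leaves the difficulty unchanged;
    a larger improvement steps one level harder, a larger decline one level
    easier, clamped to the easy..hard scale.
    """
    if not 0 <= new_score <= 100:
        raise ValueError(f"session score must be in [0, 100], got {new_score}")
    if state.last_adjust_date == today:
        return current, state
    delta = new_score - state.last_session_score
    if delta > ADAPT_DEAD_BAND:
        new_level = current.step(+1)
    elif delta < -ADAPT_DEAD_BAND:
        new_level = current.step(-1)
    else:
        new_level = current
    return new_level, AdaptationState(last_adjust_date=today, last_session_score=new_score)
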