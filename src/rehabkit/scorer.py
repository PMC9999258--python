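"""Similarity scoring against standard-movement templates and game scoring.

Each detected repetition is compared feature-by-feature with a reference
template derived from the standard movement.  The per-feature similarity is a
relative-error kernel

    s = max(0, 1 - |f - ref| / |ref|)        (absolute scale when ref == 0)

clipped to [0, 1], and the repetition's score is the weighted sum of the
similarities over the template's active feature set.  The simple (easy) mode
uses amplitude alone; the hard mode uses all five features with weights
(0.5, 0.2, 0.1, 0.1, 0.1) in the order (amp, mean, rms, jerk, strength); a
moderate mode interpolates with amplitude and RMS at (0.7, 0.3).  For
exercises without the glove the strength feature is unavailable and the hard
weights renormalize over the remaining four features.

A repetition is a *valid action* when its score reaches the difficulty
threshold (easy 0.40, moderate 0.60, hard 0.80, inclusive).  Each valid
action increments the game score by one point (one apple picked); the session
score is the percentage of valid repetitions on a 0-100 scale.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .difficulty import DifficultyLevel
from .motionfeat import FEATURE_NAMES, FeatureVector, extract_features
from .prescribe import ExerciseSpec, get_exercise
from .sigproc import segment_repetitions
from .synthgen import MotionStream, SynthParams, generate_session

#: Weighted feature sets per difficulty mode, in (amp, mean, rms, jerk, strength) order.
MODE_WEIGHTS: dict[str, dict[str, float]] = {
    "easy": {"amp": 1.0},
    "moderate": {"amp": 0.7, "rms": 0.3},
    "hard": {"amp": 0.5, "mean": 0.2, "rms": 0.1, "jerk": 0.1, "strength": 0.1},
}

#: Game points awarded per valid action.
POINTS_PER_ACTION = 1

#: Reference amplitude of the standard movement, per body segment
#: (g for limb exercises, degrees of wrist pitch for hand exercises).
REFERENCE_AMPLITUDE = {"upper": 2.0, "hand": 45.0, "lower": 2.0}


class TemplateError(ValueError):
    """Raised for malformed reference templates."""


@dataclass(frozen=True)
class ReferenceTemplate:
    """Per-exercise standard-movement feature references and weights."""

    exercise_id: str
    difficulty: str
    ref_features: dict[str, float]
    weights: dict[str, float]

    @property
    def active_set(self) -> tuple[str, ...]:
        return tuple(k for k in FEATURE_NAMES if k in self.weights)

    def validate(self) -> None:
        for k, w in self.weights.items():
            if k not in FEATURE_NAMES:
                raise TemplateError(f"unknown feature in weights: {k!r}")
            if w < 0:
                raise TemplateError(f"weight for {k!r} must be non-negative")
            if k not in self.ref_features:
                raise TemplateError(f"missing reference value for weighted feature {k!r}")
        total = sum(self.weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise TemplateError(f"weights must sum to 1, got {total}")
        for k, v in self.ref_features.items():
            if not np.isfinite(v):
                raise TemplateError(f"reference value for {k!r} must be finite")
        if self.ref_features.get("amp", 1.0) <= 0:
            raise TemplateError("reference amp must be positive")

    def to_dict(self) -> dict:
        return {
            "exercise_id": self.exercise_id,
            "difficulty": self.difficulty,
            "ref_features": self.ref_features,
            "weights": self.weights,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceTemplate":
        tpl = cls(
            exercise_id=d["exercise_id"],
            difficulty=d["difficulty"],
            ref_features=dict(d["ref_features"]),
            weights=dict(d["weights"]),
        )
        tpl.validate()
        return tpl


def mode_weights(exercise: ExerciseSpec, difficulty: str) -> dict[str, float]:
    """Difficulty-mode weights, renormalized without strength when no glove is worn."""
    weights = dict(MODE_WEIGHTS[difficulty])
    if "strength" in weights and not exercise.uses_glove:
        weights.pop("strength")
        total = sum(weights.values())
        weights = {k: w / total for k, w in weights.items()}
    return weights


def build_reference_template(
    exercise: ExerciseSpec | str,
    difficulty: str,
    params: SynthParams | None = None,
) -> ReferenceTemplate:
    """Derive a template by running the pipeline on a noise-free standard bout.

    This stands in for the feature references of the standard training video:
    the reference bout is generated at the exercise's reference amplitude with
    no noise and full smoothness, and the template stores the mean feature
    vector over its repetitions.
    """
    if isinstance(exercise, str):
        exercise = get_exercise(exercise)
    if params is None:
        params = SynthParams(
            n_reps=5,
            amplitude=REFERENCE_AMPLITUDE[exercise.segment],
            noise_sd=0.0,
            smoothness=1.0,
            seed=0,
        )
    stream = generate_session(exercise, params)
    segments = segment_repetitions(stream, exercise)
    if not segments:
        raise TemplateError("reference bout produced no repetitions")
    fvs = [extract_features(seg, exercise, stream.fs) for seg in segments]
    ref = {
        name: float(np.mean([getattr(fv, name) for fv in fvs])) for name in FEATURE_NAMES
    }
    tpl = ReferenceTemplate(
        exercise_id=exercise.id,
        difficulty=difficulty,
        ref_features=ref,
        weights=mode_weights(exercise, difficulty),
    )
    tpl.validate()
    return tpl


def feature_similarity(f: float, ref: float) -> float:
    """Relative-error similarity in [0, 1]; 1 at a perfect match."""
    if not (np.isfinite(f) and np.isfinite(ref)):
        raise ValueError(f"similarity inputs must be finite, got f={f}, ref={ref}")
    if ref == 0:
        s = 1.0 - abs(f - ref)
    else:
        s = 1.0 - abs(f - ref) / abs(ref)
    return float(min(1.0, max(0.0, s)))


def combined_score(features: FeatureVector, template: ReferenceTemplate) -> float:
    """Weighted similarity over the template's active feature set; in [0, 1]."""
    template.validate()
    score = 0.0
    for name, w in template.weights.items():
        if name == "strength" and not features.strength_available:
            sim = 0.0
        else:
            sim = feature_similarity(getattr(features, name), template.ref_features[name])
        score += w * sim
    return float(min(1.0, max(0.0, score)))


def is_valid(score: float, difficulty: DifficultyLevel) -> bool:
    """A repetition is valid when its score reaches the threshold (inclusive)."""
    return score >= difficulty.threshold


def update_game(score: int, valid: bool) -> int:
    """Valid action -> +1 point (pick an apple); invalid -> unchanged."""
    return score + POINTS_PER_ACTION if valid else score


@dataclass(frozen=True)
class RepResult:
    """Validity decision for one repetition."""

    rep_index: int
    features: FeatureVector
    similarity: float
    valid: bool


@dataclass
class SessionResult:
    """Outcome of one scored training bout."""

    exercise_id: str
    difficulty: str
    rep_results: list[RepResult] = field(default_factory=list)
    valid_count: int = 0
    game_score: int = 0
    session_score: float = 0.0  # 0-100 scale

    def to_dict(self) -> dict:
        return {
            "exercise_id": self.exercise_id,
            "difficulty": self.difficulty,
            "valid_count": self.valid_count,
            "game_score": self.game_score,
            "session_score": self.session_score,
            "rep_results": [
                {
                    "rep_index": r.rep_index,
                    "similarity": r.similarity,
                    "valid": r.valid,
                    "features": r.features.as_dict(),
                }
                for r in self.rep_results
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionResult":
        reps = [
            RepResult(
                rep_index=r["rep_index"],
                features=FeatureVector(
                    **r["features"],
                    strength_available=True,
                ),
                similarity=r["similarity"],
                valid=r["valid"],
            )
            for r in d["rep_results"]
        ]
        return cls(
            exercise_id=d["exercise_id"],
            difficulty=d["difficulty"],
            rep_results=reps,
            valid_count=d["valid_count"],
            game_score=d["game_score"],
            session_score=d["session_score"],
        )


def score_session(
    stream: MotionStream,
    template: ReferenceTemplate,
    difficulty: DifficultyLevel | None = None,
) -> SessionResult:
    """Run the full pipeline: filter -> rebase -> segment -> features -> scores.

    Deterministic for a fixed input.  ``difficulty`` defaults to the level the
    template was built for; the template must match the stream's exercise.
    """
    template.validate()
    if template.exercise_id != stream.exercise_id:
        raise ValueError(
            f"template is for {template.exercise_id!r} but stream is "
            f"{stream.exercise_id!r}"
        )
    if difficulty is None:
        difficulty = DifficultyLevel.from_name(template.difficulty)
    exercise = stream.exercise
    segments = segment_repetitions(stream, exercise) if stream.tracks else []
    rep_results = []
    game = 0
    for seg in segments:
        fv = extract_features(seg, exercise, stream.fs)
        sim = combined_score(fv, template)
        valid = is_valid(sim, difficulty)
        game = update_game(game, valid)
        rep_results.append(
            RepResult(rep_index=seg.rep_index, features=fv, similarity=sim, valid=valid)
        )
    valid_count = sum(r.valid for r in rep_results)
    total = len(rep_results)
    return SessionResult(
        exercise_id=stream.exercise_id,
        difficulty=difficulty.level,
        rep_results=rep_results,
        valid_count=valid_count,
        game_score=game,
        session_score=100.0 * valid_count / total if total else 0.0,
    )


def template_to_json(template: ReferenceTemplate, path) -> None:
    with open(path, "w") as fh:
        json.dump(template.to_dict(), fh, indent=2)


def template_from_json(path) -> ReferenceTemplate:
    with open(path) as fh:
        return ReferenceTemplate.from_dict(json.load(fh))
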