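"""Difficulty levels and their validity thresholds.

A repetition counts as a *valid action* when its weighted similarity score
against the standard-movement template reaches the threshold of the session's
difficulty level: 0.40 (easy), 0.60 (moderate) or 0.80 (hard).
"""
from __future__ import annotations

from dataclasses import dataclass

#: Validity threshold per difficulty level (fraction of perfect similarity).
DIFFICULTY_THRESHOLDS: dict[str, float] = {
    "easy": 0.40,
    "moderate": 0.60,
    "hard": 0.80,
}

#: Ordering used when stepping difficulty up or down.
DIFFICULTY_ORDER: tuple[str, ...] = ("easy", "moderate", "hard")


@dataclass(frozen=True)
class DifficultyLevel:
    """A named difficulty with its fixed validity threshold."""

    level: str
    threshold: float

    def __post_init__(self) -> None:
        if self.level not in DIFFICULTY_THRESHOLDS:
            raise ValueError(f"unknown difficulty level: {self.level!r}")
        if abs(self.threshold - DIFFICULTY_THRESHOLDS[self.level]) > 1e-12:
            raise ValueError(
                f"threshold for {self.level!r} must be "
                f"{DIFFICULTY_THRESHOLDS[self.level]}, got {self.threshold}"
            )

    @classmethod
    def from_name(cls, level: str) -> "DifficultyLevel":
        if level not in DIFFICULTY_THRESHOLDS:
            raise ValueError(f"unknown difficulty level: {level!r}")
        return cls(level=level, threshold=DIFFICULTY_THRESHOLDS[level])

    def step(self, delta: int) -> "DifficultyLevel":
        """Move ``delta`` levels up (+) or down (−), clamped to the scale ends."""
        i = DIFFICULTY_ORDER.index(self.level) + delta
        i = min(max(i, 0), len(DIFFICULTY_ORDER) - 1)
        return DifficultyLevel.from_name(DIFFICULTY_ORDER[i])


EASY = DifficultyLevel.from_name("easy")
MODERATE = DifficultyLevel.from_name("moderate")
HARD = DifficultyLevel.from_name("hard")
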