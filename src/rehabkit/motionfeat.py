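"""Per-repetition motion features.

Five scalar features summarize each repetition of the primary channel:

========  ==========================================================
AMP       max(x) - min(x): magnitude of the movement
MEAN      arithmetic mean: direction/offset of the movement
RMS       root mean square: dynamic energy of the motion
JERK      normalized mean squared derivative: smoothness (lower = smoother)
Strength  mean flex-sensor deflection from the first frame: exercise effort
========  ==========================================================

JERK is made dimensionless and amplitude-independent by normalizing the mean
squared first difference (scaled to a derivative by the sampling rate) with
``fs^2 * AMP^2``:

    J = [ (1/(N-1)) * sum_i ((x[i+1] - x[i]) * fs)^2 ] / (fs^2 * AMP(x)^2)

so J(k*x) = J(x) for any k != 0 and J = 0 for a constant signal.  Strength is
only defined when glove flex channels are present; for limb exercises the
feature is reported as 0 with an availability flag instead of raising.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .prescribe import ExerciseSpec
from .sigproc import RepetitionSegment

#: Canonical feature order used for template weights.
FEATURE_NAMES = ("amp", "mean", "rms", "jerk", "strength")


def _as_array(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError("sequence must be non-empty")
    return arr.ravel()


def amp(x) -> float:
    """Peak-to-trough span, max(x) - min(x); >= 0."""
    arr = _as_array(x)
    return float(arr.max() - arr.min())


def mean(x) -> float:
    """Arithmetic mean of the signal."""
    return float(_as_array(x).mean())


def rms(x) -> float:
    """Root mean square, sqrt(mean(x^2)); >= |mean(x)|."""
    arr = _as_array(x)
    return float(np.sqrt(np.mean(arr**2)))


def jerk(x, fs: float) -> float:
    """Normalized smoothness metric; 0 for constant signals, lower = smoother."""
    arr = _as_array(x)
    if arr.size < 2:
        raise ValueError("jerk requires at least 2 samples")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    a = amp(arr)
    if a == 0:
        return 0.0
    # normalize by amp before squaring so tiny-amplitude signals do not
    # underflow; algebraically identical to mean((diff*fs)^2) / (fs^2 * amp^2)
    return float(np.mean((np.diff(arr) / a) ** 2))


def strength(flex) -> float:
    """Mean over time of the mean flex deflection from the first frame, clipped to >= 0."""
    arr = np.asarray(flex, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.size == 0:
        raise ValueError("flex sequence must be non-empty")
    deflection = arr - arr[0]
    return float(max(0.0, deflection.mean()))


@dataclass(frozen=True)
class FeatureVector:
    """The five motion features for one repetition."""

    amp: float
    mean: float
    rms: float
    jerk: float
    strength: float
    strength_available: bool = True

    def __post_init__(self) -> None:
        values = (self.amp, self.mean, self.rms, self.jerk, self.strength)
        if not all(np.isfinite(values)):
            raise ValueError(f"feature values must be finite, got {values}")
        if self.amp < 0 or self.rms < 0 or self.jerk < 0 or self.strength < 0:
            raise ValueError("amp, rms, jerk and strength must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def extract_features(
    segment: RepetitionSegment, exercise: ExerciseSpec, fs: float
) -> FeatureVector:
    """Compute the full feature vector for one detected repetition.

    amp/mean/rms/jerk come from the segment's (filtered) primary channel;
    strength from the glove flex channels when the exercise uses the glove,
    otherwise it is 0 with ``strength_available=False``.
    """
    x = segment.primary
    if exercise.uses_glove and segment.flex is not None:
        s, avail = strength(segment.flex), True
    else:
        s, avail = 0.0, False
    return FeatureVector(
        amp=amp(x),
        mean=mean(x),
        rms=rms(x),
        jerk=jerk(x, fs),
        strength=s,
        strength_available=avail,
    )


def features_to_csv(features: list[FeatureVector], path) -> None:
    """Export feature vectors as CSV rows (rep_index, amp, mean, rms, jerk, strength)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rep_index", *FEATURE_NAMES])
        for i, fv in enumerate(features):
            writer.writerow([i] + [repr(getattr(fv, n)) for n in FEATURE_NAMES])
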