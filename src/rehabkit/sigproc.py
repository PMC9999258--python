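"""Stream preprocessing and repetition segmentation.

Three stages sit between the raw 30 Hz frames and feature extraction:

1. **Sliding filter** — a centered moving average (default window 5, about
   0.17 s) that suppresses measurement noise; at the sequence edges the
   window is truncated to the available samples, so output length equals
   input length and constants pass through unchanged.
2. **Orientation rebasing** — the sensors run in headless mode: whatever pose
   a device is in at movement onset is taken as its reference origin.  The
   first (filtered) accelerometer and magnetometer vectors define a TRIAD
   frame (gravity up, magnetic heading fixing the rotation about gravity);
   every accel/gyro/mag vector is re-expressed in that frame.  A stream that
   was pre-rotated by any fixed rotation therefore rebases to the same
   result, which is what makes the features placement-invariant.
3. **Segmentation** — repetitions are delimited by hysteresis thresholding of
   the filtered primary channel: a segment opens when the signal rises above
   baseline + ``threshold_frac`` x range and closes when it falls below half
   that excursion; boundaries are then extended outward to where the signal
   rejoins the baseline (within 1% of range), and segments shorter than
   ``min_duration`` are dropped.

The primary channel per exercise is the resultant acceleration magnitude of
the distal IMU for limb exercises, and a wrist pitch angle (degrees, from the
rebased glove accelerometer) for hand exercises.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .prescribe import ExerciseSpec
from .synthgen import DeviceTrack, MotionStream, PRIMARY_ROLE

#: Default sliding-filter window (frames); ~0.17 s at 30 Hz.
DEFAULT_FILTER_WINDOW = 5

#: Minimum repetition length in frames (0.5 s at 30 Hz).
MIN_SEGMENT_FRAMES = 15


def sliding_filter(signal, window: int = DEFAULT_FILTER_WINDOW) -> np.ndarray:
    """Centered moving average with edge truncation.

    ``window`` must be odd so the kernel is centered; near the edges the
    average runs over the samples that exist, so the output has the same
    length as the input and a constant input is returned unchanged.
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("signal must be non-empty")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window == 1:
        return x.copy()
    kernel = np.ones(window)
    half = window // 2
    sums = np.convolve(x, kernel, mode="full")[half : half + x.size]
    counts = np.convolve(np.ones_like(x), kernel, mode="full")[half : half + x.size]
    return sums / counts


def _triad(accel: np.ndarray, mag: np.ndarray) -> np.ndarray:
    """Rotation matrix whose rows are the body-initial axes (x east-ish, z up)."""
    a = np.asarray(accel, dtype=float)
    m = np.asarray(mag, dtype=float)
    na = np.linalg.norm(a)
    if na < 1e-9:
        raise ValueError("initial accelerometer vector is degenerate (near zero)")
    z = a / na
    m_perp = m - (m @ z) * z
    nm = np.linalg.norm(m_perp)
    if nm < 1e-9:
        raise ValueError("initial magnetometer vector is parallel to gravity")
    x = m_perp / nm
    y = np.cross(z, x)
    return np.vstack([x, y, z])


def rebase_orientation(
    stream: MotionStream, filter_window: int = DEFAULT_FILTER_WINDOW
) -> MotionStream:
    """Re-express every device's vector channels relative to its initial pose.

    The initial pose is taken from the first sample of the filtered accel and
    mag channels ("headless mode": the pose at movement onset becomes the
    origin).  Flex channels are scalar and pass through unchanged.
    """
    if not stream.tracks or stream.n_frames == 0:
        raise ValueError("cannot rebase an empty stream")
    new_tracks = {}
    for role, tr in stream.tracks.items():
        a0 = np.array([sliding_filter(tr.accel[:, i], filter_window)[0] for i in range(3)])
        m0 = np.array([sliding_filter(tr.mag[:, i], filter_window)[0] for i in range(3)])
        rot = _triad(a0, m0)
        new_tracks[role] = DeviceTrack(
            role=role,
            t=tr.t.copy(),
            accel=tr.accel @ rot.T,
            gyro=tr.gyro @ rot.T,
            mag=tr.mag @ rot.T,
            flex=tr.flex.copy() if tr.flex is not None else None,
        )
    return MotionStream(
        exercise_id=stream.exercise_id,
        fs=stream.fs,
        tracks=new_tracks,
        ground_truth=list(stream.ground_truth),
        params=stream.params,
        rep_scales=stream.rep_scales,
    )


def primary_channel(stream: MotionStream, exercise: ExerciseSpec | None = None) -> np.ndarray:
    """Scalar channel that drives segmentation and the Table-of-features math.

    Limb exercises use the resultant acceleration magnitude of the distal IMU
    (rotation-invariant by construction); hand exercises use the wrist pitch
    angle in degrees, i.e. the angle between the rebased glove accelerometer
    vector and the initial gravity axis.
    """
    exercise = exercise or stream.exercise
    track = stream.tracks[PRIMARY_ROLE[exercise.segment]]
    if exercise.segment == "hand":
        norms = np.linalg.norm(track.accel, axis=1)
        norms = np.where(norms < 1e-12, 1.0, norms)
        cos_pitch = np.clip(track.accel[:, 2] / norms, -1.0, 1.0)
        return np.degrees(np.arccos(cos_pitch))
    return np.linalg.norm(track.accel, axis=1)


@dataclass
class RepetitionSegment:
    """One detected repetition: half-open frame indices plus channel slices."""

    start_index: int
    end_index: int
    rep_index: int
    primary: np.ndarray  # filtered primary-channel slice
    flex: np.ndarray | None = None  # glove flex slice, if present

    def __post_init__(self) -> None:
        if self.end_index - self.start_index < MIN_SEGMENT_FRAMES:
            raise ValueError(
                f"segment [{self.start_index}, {self.end_index}) shorter than "
                f"{MIN_SEGMENT_FRAMES} frames"
            )

    @property
    def n_frames(self) -> int:
        return self.end_index - self.start_index


def _hysteresis_segments(
    filtered: np.ndarray, threshold_frac: float, min_frames: int
) -> list[tuple[int, int]]:
    # Robust stream range: percentiles instead of min/max so single spikes
    # (noise) do not inflate the thresholds and near-threshold repetitions
    # are not lost to the peak sample of the largest one.
    lo_q, hi_q = np.percentile(filtered, [1.0, 99.0])
    base = float(lo_q)
    span = float(hi_q) - base
    if span <= 0:
        return []
    hi = base + threshold_frac * span
    lo = base + 0.5 * threshold_frac * span
    edge = base + 0.01 * span
    bounds: list[tuple[int, int]] = []
    inside = False
    start = 0
    for i, v in enumerate(filtered):
        if not inside and v >= hi:
            inside = True
            start = i
        elif inside and v < lo:
            bounds.append((start, i))
            inside = False
    if inside:
        bounds.append((start, len(filtered)))
    # extend each detection outward to where the signal rejoins the baseline
    extended: list[tuple[int, int]] = []
    for start, end in bounds:
        left_limit = extended[-1][1] if extended else 0
        while start > left_limit and filtered[start - 1] > edge:
            start -= 1
        while end < len(filtered) and filtered[end] > edge:
            end += 1
        if end - start >= min_frames:
            extended.append((start, end))
    return extended


def segment_repetitions(
    stream: MotionStream,
    exercise: ExerciseSpec | None = None,
    threshold_frac: float = 0.3,
    min_duration: float = 0.5,
    filter_window: int = DEFAULT_FILTER_WINDOW,
    rebase: bool = True,
) -> list[RepetitionSegment]:
    """Detect repetitions in a stream; returns a possibly-empty ordered list.

    The stream is rebased, its primary channel extracted and filtered, and the
    hysteresis rule above applied.  A flat stream yields no segments.
    """
    exercise = exercise or stream.exercise
    if not stream.tracks or stream.n_frames == 0:
        return []
    if rebase:
        stream = rebase_orientation(stream, filter_window)
    raw = primary_channel(stream, exercise)
    filtered = sliding_filter(raw, filter_window)
    min_frames = max(MIN_SEGMENT_FRAMES, int(round(min_duration * stream.fs)))
    bounds = _hysteresis_segments(filtered, threshold_frac, min_frames)
    glove = stream.tracks.get("glove")
    segments = []
    for k, (start, end) in enumerate(bounds):
        segments.append(
            RepetitionSegment(
                start_index=start,
                end_index=end,
                rep_index=k,
                primary=filtered[start:end],
                flex=glove.flex[start:end] if glove is not None and glove.flex is not None else None,
            )
        )
    return segments


def segments_to_csv(segments, fs: float, path) -> None:
    """Debug dump: one row per segment with start/end times."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rep_index", "start_t", "end_t"])
        for seg in segments:
            writer.writerow(
                [seg.rep_index, f"{seg.start_index / fs:.4f}", f"{seg.end_index / fs:.4f}"]
            )
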