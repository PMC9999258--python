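"""Synthetic wearable-sensor streams with ground-truth repetition labels.

The wearable kit consists of two 9-axis IMU modules (strapped to upper/lower
arm for upper-limb exercises, thigh/calf for lower-limb exercises) and a
rehabilitation glove with one IMU plus five flex sensors, all sampled at
30 Hz.  This module emulates those streams for a prescribed exercise so that
segmentation, feature extraction and scoring can be exercised and validated
without hardware.

The canonical repetition profile is a raised cosine (a smooth out-and-back
movement): for a repetition of duration ``T`` and amplitude ``A``,

    s(t) = A/2 * (1 - cos(2*pi*t/T)),   0 <= t < T,

which starts and ends at the baseline and reaches peak-to-trough span ``A``
exactly.  Reduced ``smoothness`` superimposes band-limited 4-8 Hz tremor
harmonics scaled by ``1 - smoothness``, inflating the jerk metric without
changing the amplitude materially.  Gaussian measurement noise of standard
deviation ``noise_sd`` (in the primary-signal units) is added on top.

Every stream carries its ground truth (repetition windows, per-repetition
amplitude, intended validity), which exists only in synthesis and is what the
test suite measures recovery against.
"""
from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .prescribe import ExerciseSpec, get_exercise

#: Nominal sampling rate of every wearable device, Hz.
FS = 30.0

#: Device whose channel drives the game for each body segment (the distal one).
PRIMARY_ROLE = {"upper": "lower_arm", "hand": "glove", "lower": "calf"}

#: Resting magnetic-field direction in the sensor frame (normalized units).
_MAG_REST = np.array([0.6, 0.0, 0.8])

#: Fraction of the flex range swept by a full-amplitude repetition.
_FLEX_SPAN = 0.8
_FLEX_BASE = 0.1


class ParameterError(ValueError):
    """Raised for invalid synthesis parameters."""


@dataclass(frozen=True)
class SynthParams:
    """Controls for one synthetic training bout.

    ``amplitude`` is in the primary-signal units of the exercise: resultant
    acceleration (g) for limb exercises, wrist pitch (degrees) for hand
    exercises.  ``noise_sd`` is in the same units.
    """

    n_reps: int = 5
    amplitude: float = 2.0
    rep_duration: float = 3.0
    pause_duration: float = 1.0
    noise_sd: float = 0.0
    smoothness: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_reps < 0:
            raise ParameterError(f"n_reps must be >= 0, got {self.n_reps}")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.rep_duration < 0.5:
            raise ParameterError(
                f"rep_duration must be >= 0.5 s, got {self.rep_duration}"
            )
        if self.pause_duration < 0:
            raise ParameterError("pause_duration must be >= 0")
        if not 0 <= self.smoothness <= 1:
            raise ParameterError("smoothness must lie in [0, 1]")
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "amplitude": self.amplitude,
            "rep_duration": self.rep_duration,
            "pause_duration": self.pause_duration,
            "noise_sd": self.noise_sd,
            "smoothness": self.smoothness,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class SensorFrame:
    """One 30 Hz sample from one worn device."""

    t: float
    device_role: str
    accel: tuple[float, float, float]
    gyro: tuple[float, float, float]
    mag: tuple[float, float, float]
    flex: tuple[float, float, float, float, float] | None = None


@dataclass
class DeviceTrack:
    """Column-wise storage of one device's frames (time, accel, gyro, mag, flex)."""

    role: str
    t: np.ndarray  # (N,) seconds from bout start
    accel: np.ndarray  # (N, 3) in g
    gyro: np.ndarray  # (N, 3) in deg/s
    mag: np.ndarray  # (N, 3) normalized
    flex: np.ndarray | None = None  # (N, 5) in [0, 1]; glove only

    def __len__(self) -> int:
        return len(self.t)

    def frames(self) -> Iterator[SensorFrame]:
        for i in range(len(self.t)):
            yield SensorFrame(
                t=float(self.t[i]),
                device_role=self.role,
                accel=tuple(self.accel[i]),
                gyro=tuple(self.gyro[i]),
                mag=tuple(self.mag[i]),
                flex=tuple(self.flex[i]) if self.flex is not None else None,
            )


@dataclass(frozen=True)
class RepWindow:
    """Ground-truth repetition window (half-open frame indices)."""

    start: int
    end: int
    amplitude: float
    intended_valid: bool = True


@dataclass
class MotionStream:
    """Frames of all devices for one bout, with synthetic ground truth."""

    exercise_id: str
    fs: float
    tracks: dict[str, DeviceTrack]
    ground_truth: list[RepWindow] = field(default_factory=list)
    # Synthesis provenance; lets degrade_repetitions rebuild with identical noise.
    params: SynthParams | None = None
    rep_scales: tuple[float, ...] | None = None

    @property
    def exercise(self) -> ExerciseSpec:
        return get_exercise(self.exercise_id)

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.tracks.values()))) if self.tracks else 0

    def primary_track(self) -> DeviceTrack:
        return self.tracks[PRIMARY_ROLE[self.exercise.segment]]


def _profile(
    params: SynthParams, fs: float, rep_scales: Sequence[float], rng: np.random.Generator
) -> tuple[np.ndarray, list[RepWindow]]:
    """Noise-free primary-channel profile plus ground-truth windows."""
    rep_frames = int(round(params.rep_duration * fs))
    pause_frames = int(round(params.pause_duration * fs))
    n = params.n_reps
    total = pause_frames + n * (rep_frames + pause_frames)
    total = max(total, pause_frames + rep_frames)  # at least a short flat bout
    s = np.zeros(total)
    windows: list[RepWindow] = []
    # Tremor harmonics are drawn even when unused so the rng stream (and hence
    # the additive noise drawn after it) does not depend on smoothness.
    tremor_f = rng.uniform(4.0, 8.0, size=2)
    tremor_phi = rng.uniform(0.0, 2 * math.pi, size=2)
    tremor_gain = 0.15 * (1.0 - params.smoothness)
    tau = np.arange(rep_frames) / fs
    base = 0.5 * params.amplitude * (1.0 - np.cos(2 * math.pi * np.arange(rep_frames) / rep_frames))
    envelope = base / params.amplitude if params.amplitude > 0 else np.zeros(rep_frames)
    for k in range(n):
        start = pause_frames + k * (rep_frames + pause_frames)
        rep = base.copy()
        if tremor_gain > 0:
            tremor = np.zeros(rep_frames)
            for f, phi in zip(tremor_f, tremor_phi):
                tremor += np.sin(2 * math.pi * f * tau + phi)
            # envelope keeps the tremor from moving the rep boundaries
            rep = rep + tremor_gain * params.amplitude * tremor * envelope
        scale = rep_scales[k]
        s[start : start + rep_frames] = scale * rep
        windows.append(
            RepWindow(
                start=start,
                end=start + rep_frames,
                amplitude=scale * params.amplitude,
                intended_valid=scale >= 1.0,
            )
        )
    return s, windows


def _limb_tracks(
    roles: tuple[str, str],
    s: np.ndarray,
    t: np.ndarray,
    fs: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> dict[str, DeviceTrack]:
    """Proximal + distal IMU tracks; motion rides on gravity along z."""
    proximal, distal = roles
    tracks: dict[str, DeviceTrack] = {}
    for role, gain in ((proximal, 0.5), (distal, 1.0)):
        accel = np.zeros((len(s), 3))
        accel[:, 2] = 1.0 + gain * s  # 1 g gravity plus motion
        accel += rng.normal(0.0, noise_sd, size=accel.shape)
        gyro = np.zeros((len(s), 3))
        gyro[:, 1] = np.gradient(gain * s, 1.0 / fs) * 15.0  # plausible deg/s scale
        gyro += rng.normal(0.0, 10.0 * noise_sd, size=gyro.shape)
        mag = np.tile(_MAG_REST, (len(s), 1))
        mag += rng.normal(0.0, 0.01 * noise_sd, size=mag.shape)
        tracks[role] = DeviceTrack(role=role, t=t, accel=accel, gyro=gyro, mag=mag)
    return tracks


def _glove_track(
    s: np.ndarray,
    t: np.ndarray,
    fs: float,
    amplitude: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> DeviceTrack:
    """Glove IMU + flex channels; ``s`` is the wrist pitch angle in degrees."""
    theta = s + rng.normal(0.0, noise_sd, size=len(s))
    theta_rad = np.radians(theta)
    accel = np.column_stack(
        [np.sin(theta_rad), np.zeros(len(s)), np.cos(theta_rad)]
    )  # unit gravity tilted by the pitch angle
    gyro = np.zeros((len(s), 3))
    gyro[:, 1] = np.gradient(theta, 1.0 / fs)
    mag = np.tile(_MAG_REST, (len(s), 1))
    span = amplitude if amplitude > 0 else 1.0
    norm = np.clip(s / span, 0.0, None)
    flex = _FLEX_BASE + _FLEX_SPAN * np.tile(norm[:, None], (1, 5))
    flex += rng.normal(0.0, _FLEX_SPAN * noise_sd / span, size=flex.shape)
    flex = np.clip(flex, 0.0, 1.0)
    return DeviceTrack(role="glove", t=t, accel=accel, gyro=gyro, mag=mag, flex=flex)


def _build(
    exercise: ExerciseSpec, params: SynthParams, rep_scales: Sequence[float]
) -> MotionStream:
    rng = np.random.default_rng(params.seed)
    s, windows = _profile(params, FS, rep_scales, rng)
    t = np.arange(len(s)) / FS
    if exercise.segment == "upper":
        tracks = _limb_tracks(("upper_arm", "lower_arm"), s, t, FS, params.noise_sd, rng)
    elif exercise.segment == "lower":
        tracks = _limb_tracks(("thigh", "calf"), s, t, FS, params.noise_sd, rng)
    else:  # hand
        tracks = {
            "glove": _glove_track(s, t, FS, params.amplitude, params.noise_sd, rng)
        }
    return MotionStream(
        exercise_id=exercise.id,
        fs=FS,
        tracks=tracks,
        ground_truth=windows,
        params=params,
        rep_scales=tuple(rep_scales),
    )


def generate_session(exercise: ExerciseSpec | str, params: SynthParams) -> MotionStream:
    """Generate one labeled training bout for ``exercise``.

    Identical ``params`` (including ``seed``) yield bit-identical streams.
    """
    if isinstance(exercise, str):
        exercise = get_exercise(exercise)
    params.validate()
    return _build(exercise, params, rep_scales=(1.0,) * params.n_reps)


def degrade_repetitions(
    stream: MotionStream, indices: set[int] | Sequence[int], factor: float
) -> MotionStream:
    """Rescale the listed ground-truth repetitions by ``factor`` in [0, 1).

    The stream is rebuilt from its synthesis parameters with the same seed, so
    measurement noise is unchanged and only the listed repetitions shrink.
    Their ground-truth ``intended_valid`` flags flip to False.
    """
    if stream.params is None or stream.rep_scales is None:
        raise ParameterError("stream does not carry synthesis parameters")
    if not 0 <= factor < 1:
        raise ParameterError(f"factor must lie in [0, 1), got {factor}")
    indices = set(indices)
    n = len(stream.rep_scales)
    bad = [i for i in indices if not 0 <= i < n]
    if bad:
        raise IndexError(f"repetition indices out of range: {sorted(bad)}")
    scales = tuple(
        factor * sc if i in indices else sc for i, sc in enumerate(stream.rep_scales)
    )
    return _build(stream.exercise, stream.params, scales)


# ---------------------------------------------------------------------------
# Serialization: JSON-lines (one frame per line) and wide CSV.

def to_jsonl(stream: MotionStream, path) -> None:
    """Write a stream as JSON-lines: a metadata header line, then one frame per line."""
    meta = {
        "type": "meta",
        "exercise_id": stream.exercise_id,
        "fs": stream.fs,
        "ground_truth": [
            {
                "start": w.start,
                "end": w.end,
                "amplitude": w.amplitude,
                "intended_valid": w.intended_valid,
            }
            for w in stream.ground_truth
        ],
        "params": stream.params.to_dict() if stream.params else None,
        "rep_scales": list(stream.rep_scales) if stream.rep_scales else None,
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(meta) + "\n")
        for role in sorted(stream.tracks):
            for fr in stream.tracks[role].frames():
                rec = {
                    "device": fr.device_role,
                    "t": fr.t,
                    "accel": list(fr.accel),
                    "gyro": list(fr.gyro),
                    "mag": list(fr.mag),
                }
                if fr.flex is not None:
                    rec["flex"] = list(fr.flex)
                fh.write(json.dumps(rec) + "\n")


def from_jsonl(path) -> MotionStream:
    """Read a stream written by :func:`to_jsonl`."""
    with open(path) as fh:
        meta = json.loads(fh.readline())
        if meta.get("type") != "meta":
            raise ValueError("missing metadata header line")
        per_role: dict[str, list[dict]] = {}
        for line in fh:
            rec = json.loads(line)
            per_role.setdefault(rec["device"], []).append(rec)
    tracks = {}
    for role, recs in per_role.items():
        tracks[role] = DeviceTrack(
            role=role,
            t=np.array([r["t"] for r in recs]),
            accel=np.array([r["accel"] for r in recs]),
            gyro=np.array([r["gyro"] for r in recs]),
            mag=np.array([r["mag"] for r in recs]),
            flex=np.array([r["flex"] for r in recs]) if "flex" in recs[0] else None,
        )
    params = SynthParams(**meta["params"]) if meta.get("params") else None
    return MotionStream(
        exercise_id=meta["exercise_id"],
        fs=meta["fs"],
        tracks=tracks,
        ground_truth=[
            RepWindow(
                start=w["start"],
                end=w["end"],
                amplitude=w["amplitude"],
                intended_valid=w["intended_valid"],
            )
            for w in meta["ground_truth"]
        ],
        params=params,
        rep_scales=tuple(meta["rep_scales"]) if meta.get("rep_scales") else None,
    )


def to_csv(stream: MotionStream, path) -> None:
    """Write a stream as a wide CSV: one row per timestamp, one column per channel."""
    roles = sorted(stream.tracks)
    header = ["t"]
    for role in roles:
        for ch in ("accel", "gyro", "mag"):
            header += [f"{role}_{ch}_{ax}" for ax in "xyz"]
        if stream.tracks[role].flex is not None:
            header += [f"{role}_flex_{i}" for i in range(5)]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        n = stream.n_frames
        t = stream.tracks[roles[0]].t
        for i in range(n):
            row = [f"{t[i]:.6f}"]
            for role in roles:
                tr = stream.tracks[role]
                for arr in (tr.accel, tr.gyro, tr.mag):
                    row += [repr(float(v)) for v in arr[i]]
                if tr.flex is not None:
                    row += [repr(float(v)) for v in tr.flex[i]]
            writer.writerow(row)
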