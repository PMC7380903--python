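"""Synthetic wrist-IMU recordings of home-rehabilitation exercises.

Generates labeled 6-axis sessions for four bilateral upper-limb
exercises plus rest, standing in for wrist-worn smartwatch recordings
of stroke survivors.  Each exercise is modeled as quasi-periodic wrist
rotation about a class-specific axis,

    theta(t) = A * sin(2*pi*f*t),

so the gyroscope reads the analytic angular velocity ``theta'(t) * u``
and the accelerometer reads gravity rotated into the device frame
(specific-force convention: a flat, stationary device reads +g on its
z channel) plus a small class-specific linear-acceleration term.
Per-subject idiosyncrasy — amplitude scale, tempo, rotation-axis tilt,
mounting orientation, sensor noise level — is drawn once per subject
from population distributions, which is what makes personally trained
classifiers outperform population-pooled ones on these data.

All randomness is derived from ``(config.seed, subject_id)`` so every
session is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import math
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .classes import EXERCISES, CHANNELS, ExerciseClass
from .sessions import DEFAULT_RATE_HZ, LabeledSession

import pandas as pd

GRAVITY = 9.81  # m/s^2


@dataclasses.dataclass(frozen=True)
class ClassKinematics:
    """Default motion model of one exercise class.

    amplitude_rad : peak rotation angle A
    freq_hz       : repetition frequency f
    axis          : unit rotation axis in the device frame
    linear_amp    : peak linear-acceleration term (m/s^2)
    linear_dir    : direction of the linear term in the device frame
    """

    amplitude_rad: float
    freq_hz: float
    axis: tuple[float, float, float]
    linear_amp: float
    linear_dir: tuple[float, float, float]


def _unit(v: Sequence[float]) -> tuple[float, float, float]:
    a = np.asarray(v, dtype=float)
    a = a / np.linalg.norm(a)
    return (float(a[0]), float(a[1]), float(a[2]))


# Slow rehabilitation tempos and distinct axes; every axis has a
# component perpendicular to gravity so orientation change is visible
# to the accelerometer as well as the gyroscope.
CLASS_KINEMATICS: Mapping[ExerciseClass, ClassKinematics] = {
    ExerciseClass.BILATERAL_FLEXION: ClassKinematics(
        math.radians(80.0), 0.25, _unit((1, 0, 0)), 0.6, _unit((0, 0, 1))
    ),
    ExerciseClass.WALL_PUSH: ClassKinematics(
        math.radians(30.0), 0.50, _unit((0, 1, 0)), 0.8, _unit((1, 0, 0))
    ),
    ExerciseClass.ACTIVE_SCAPULA: ClassKinematics(
        math.radians(40.0), 0.40, _unit((1, -1, 0)), 0.5, _unit((0, 1, 0))
    ),
    ExerciseClass.TOWEL_SLIDE: ClassKinematics(
        math.radians(60.0), 0.33, _unit((1, 0, 1)), 0.7, _unit((0, 1, 1))
    ),
}


@dataclasses.dataclass
class SimConfig:
    """Population-level simulation parameters.

    The defaults define the benchmark conditions used throughout the
    package: 10 Hz sampling, 4 s per exercise repetition with 2 s rest
    between repetitions, consumer-watch noise magnitudes, and enough
    inter-subject spread (10 deg axis tilt SD, 0.2 amplitude-scale SD,
    15% tempo SD, 40 deg strap-mounting SD — a watch body can sit
    almost anywhere around the wrist) that pooled models face real
    heterogeneity while personally trained models do not.
    """

    rate: float = DEFAULT_RATE_HZ
    gravity: float = GRAVITY
    rep_duration_s: float = 4.0
    rest_s: float = 2.0
    seed: int = 0
    # population distribution of subject profiles
    amplitude_scale_mean: float = 1.0
    amplitude_scale_sd: float = 0.2
    freq_rel_sd: float = 0.15
    axis_perturb_sd_rad: float = math.radians(10.0)
    orientation_offset_sd_rad: float = math.radians(40.0)
    accel_noise_mean: float = 0.3  # m/s^2
    accel_noise_sd: float = 0.05
    gyro_noise_mean: float = 0.05  # rad/s
    gyro_noise_sd: float = 0.01
    # resting drift (slow orientation wobble during NO_EXERCISE)
    drift_amp_rad: float = 0.05
    drift_freq_hz: float = 0.02

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        for name in (
            "amplitude_scale_sd",
            "freq_rel_sd",
            "axis_perturb_sd_rad",
            "orientation_offset_sd_rad",
            "accel_noise_sd",
            "gyro_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"population SD {name} must be >= 0")
        if self.rep_duration_s <= 0 or self.rest_s < 0:
            raise ValueError("durations must be positive (rest may be 0)")


@dataclasses.dataclass
class SubjectProfile:
    """One subject's idiosyncratic motion characteristics."""

    subject_id: str
    amplitude_scale: dict[ExerciseClass, float]
    freq_hz: dict[ExerciseClass, float]
    axis_perturb: np.ndarray  # small 3-vector, rad
    orientation_offset: np.ndarray  # rotation vector, rad
    accel_noise_sd: float
    gyro_noise_sd: float

    def __post_init__(self) -> None:
        if self.accel_noise_sd < 0 or self.gyro_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        for c, s in self.amplitude_scale.items():
            if not (0 < s <= 3):
                raise ValueError(f"amplitude scale for {c.name} out of (0, 3]: {s}")
        for c, f in self.freq_hz.items():
            if not (0.05 < f <= 2.0):
                raise ValueError(f"frequency for {c.name} out of (0.05, 2.0] Hz: {f}")


@dataclasses.dataclass
class ExerciseSchedule:
    """Ordered (class, duration in seconds) segments of one session."""

    segments: list[tuple[ExerciseClass, float]]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule must be non-empty")
        for cls, dur in self.segments:
            if cls not in ExerciseClass:
                raise ValueError(f"unknown exercise class {cls!r}")
            if dur <= 0:
                raise ValueError(f"segment duration must be > 0, got {dur}")

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.segments))

    @classmethod
    def training_session(
        cls,
        reps: int = 15,
        rep_duration_s: float = 4.0,
        rest_s: float = 2.0,
        exercises: Sequence[ExerciseClass] = EXERCISES,
    ) -> "ExerciseSchedule":
        """One acquisition session: each exercise repeated ``reps``
        times, repetitions separated by rest, rest at start and end."""
        if reps < 1:
            raise ValueError("reps must be >= 1")
        segments: list[tuple[ExerciseClass, float]] = [
            (ExerciseClass.NO_EXERCISE, rest_s)
        ]
        for ex in exercises:
            for _ in range(reps):
                segments.append((ex, rep_duration_s))
                segments.append((ExerciseClass.NO_EXERCISE, rest_s))
        return cls(segments=segments)


def _stable_hash(text: str) -> int:
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big")


def _rng_for(config: SimConfig, subject_id: str, stream: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence([int(config.seed), _stable_hash(subject_id), stream])
    return np.random.default_rng(ss)


def _trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float
) -> float:
    """One truncated-normal draw; degenerate SD returns the mean."""
    if sd == 0:
        return float(np.clip(mean, low, high))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low < x <= high:
            return float(x)
    return float(np.clip(mean, low, high))


def sample_subject_profile(config: SimConfig, subject_id: str) -> SubjectProfile:
    """Draw one subject's profile from the population distributions.

    Deterministic given ``(config.seed, subject_id)``; positive
    quantities use truncated normals so invariants always hold.
    """
    rng = _rng_for(config, subject_id, stream=0)
    amp = {
        c: _trunc_normal(rng, config.amplitude_scale_mean, config.amplitude_scale_sd, 0.0, 3.0)
        for c in EXERCISES
    }
    freq = {
        c: _trunc_normal(
            rng,
            CLASS_KINEMATICS[c].freq_hz,
            CLASS_KINEMATICS[c].freq_hz * config.freq_rel_sd,
            0.05,
            2.0,
        )
        for c in EXERCISES
    }
    axis_perturb = (
        rng.normal(0.0, config.axis_perturb_sd_rad, size=3)
        if config.axis_perturb_sd_rad > 0
        else np.zeros(3)
    )
    orientation_offset = (
        rng.normal(0.0, config.orientation_offset_sd_rad, size=3)
        if config.orientation_offset_sd_rad > 0
        else np.zeros(3)
    )
    accel_sd = _trunc_normal(rng, config.accel_noise_mean, config.accel_noise_sd, 0.0, 10.0)
    gyro_sd = _trunc_normal(rng, config.gyro_noise_mean, config.gyro_noise_sd, 0.0, 10.0)
    if config.accel_noise_mean == 0 and config.accel_noise_sd == 0:
        accel_sd = 0.0
    if config.gyro_noise_mean == 0 and config.gyro_noise_sd == 0:
        gyro_sd = 0.0
    return SubjectProfile(
        subject_id=subject_id,
        amplitude_scale=amp,
        freq_hz=freq,
        axis_perturb=axis_perturb,
        orientation_offset=orientation_offset,
        accel_noise_sd=accel_sd,
        gyro_noise_sd=gyro_sd,
    )


def _segment_signals(
    cls: ExerciseClass,
    t: np.ndarray,
    profile: SubjectProfile,
    config: SimConfig,
    r_mount: Rotation,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (accel, gyro) device-frame signals for one segment;
    ``t`` is local time starting at 0.

    The motion model lives in the arm frame; ``r_mount`` is the fixed
    arm-to-device strap rotation, so a subject's mounting offset
    rotates both the gravity pattern and the angular-velocity axis as
    seen by the sensors.
    """
    g_world = np.array([0.0, 0.0, config.gravity])
    n = t.size
    if cls is ExerciseClass.NO_EXERCISE:
        amp = config.drift_amp_rad
        if amp > 0:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            phase = rng.uniform(0, 2 * math.pi)
            omega = 2 * math.pi * config.drift_freq_hz
            theta = amp * np.sin(omega * t + phase)
            dtheta = amp * omega * np.cos(omega * t + phase)
        else:
            axis = np.array([1.0, 0.0, 0.0])
            theta = np.zeros(n)
            dtheta = np.zeros(n)
        lin = np.zeros((n, 3))
    else:
        kin = CLASS_KINEMATICS[cls]
        axis = np.asarray(kin.axis) + profile.axis_perturb
        axis = axis / np.linalg.norm(axis)
        a = kin.amplitude_rad * profile.amplitude_scale[cls]
        f = profile.freq_hz[cls]
        omega = 2 * math.pi * f
        theta = a * np.sin(omega * t)
        dtheta = a * omega * np.cos(omega * t)
        # repetitions accelerate and decelerate twice per cycle
        lin = (
            kin.linear_amp
            * np.sin(2 * omega * t)[:, None]
            * np.asarray(kin.linear_dir)[None, :]
        )

    # arm attitude R_arm(t) = exp(theta [axis]x); device = arm * mount
    r_motion = Rotation.from_rotvec(theta[:, None] * axis[None, :])
    r_device = r_motion * r_mount
    # specific force: gravity seen in the device frame (+g on z at rest,
    # identity mounting)
    accel = r_device.inv().apply(g_world) + r_mount.inv().apply(lin)
    gyro = r_mount.inv().apply(dtheta[:, None] * axis[None, :])
    return accel, gyro


def simulate_session(
    profile: SubjectProfile,
    schedule: ExerciseSchedule,
    config: SimConfig,
    date: datetime.date = datetime.date(2024, 1, 1),
    stream: int = 0,
) -> LabeledSession:
    """Render one labeled session from a schedule.

    Each scheduled segment contributes ``round(duration * rate)``
    samples; gyroscope output is the analytic angular velocity plus
    Gaussian noise, accelerometer output the device-frame specific
    force plus a small class-specific linear term and Gaussian noise.
    NO_EXERCISE segments hold the resting orientation with a slow,
    small-amplitude wobble.  Bit-reproducible for fixed
    ``(config.seed, profile.subject_id, schedule, stream)``.
    """
    rng = _rng_for(config, profile.subject_id, stream=1 + stream)
    r_mount = (
        Rotation.from_rotvec(profile.orientation_offset)
        if np.any(profile.orientation_offset)
        else Rotation.identity()
    )

    accel_parts: list[np.ndarray] = []
    gyro_parts: list[np.ndarray] = []
    label_parts: list[np.ndarray] = []
    dt = 1.0 / config.rate
    for cls, dur in schedule.segments:
        n = int(round(dur * config.rate))
        if n <= 0:
            raise ValueError(f"segment ({cls.name}, {dur}s) yields no samples")
        t_local = np.arange(n) * dt
        accel, gyro = _segment_signals(cls, t_local, profile, config, r_mount, rng)
        if profile.accel_noise_sd > 0:
            accel = accel + rng.normal(0.0, profile.accel_noise_sd, size=accel.shape)
        if profile.gyro_noise_sd > 0:
            gyro = gyro + rng.normal(0.0, profile.gyro_noise_sd, size=gyro.shape)
        accel_parts.append(accel)
        gyro_parts.append(gyro)
        label_parts.append(np.full(n, int(cls), dtype=int))

    accel = np.concatenate(accel_parts)
    gyro = np.concatenate(gyro_parts)
    labels = np.concatenate(label_parts)
    n_total = labels.size
    data = pd.DataFrame(
        np.hstack([accel, gyro]), columns=list(CHANNELS)
    )
    data.insert(0, "t", np.arange(n_total) * dt)
    data["label"] = labels
    return LabeledSession(
        subject_id=profile.subject_id, date=date, data=data, rate=config.rate
    )


def simulate_training_acquisition(
    profile: SubjectProfile,
    config: SimConfig,
    reps: int = 15,
    sessions: int = 2,
    start_date: datetime.date = datetime.date(2024, 1, 1),
) -> list[LabeledSession]:
    """Emulate the supervised training-data acquisition protocol.

    Each of the four exercises is repeated ``reps`` times in each of
    ``sessions`` sessions with rest interleaved, giving
    ``4 * sessions * reps`` labeled exercise attempts (120 under the
    default 15 x 2 protocol).
    """
    if reps < 1 or sessions < 1:
        raise ValueError("reps and sessions must be >= 1")
    schedule = ExerciseSchedule.training_session(
        reps=reps, rep_duration_s=config.rep_duration_s, rest_s=config.rest_s
    )
    return [
        simulate_session(
            profile,
            schedule,
            config,
            date=start_date + datetime.timedelta(days=i),
            stream=i,
        )
        for i in range(sessions)
    ]


def count_attempts(sessions: Sequence[LabeledSession]) -> int:
    """Number of contiguous non-rest label runs across sessions — one
    per exercise attempt."""
    total = 0
    for sess in sessions:
        labels = sess.labels
        boundaries = np.flatnonzero(np.diff(labels) != 0) + 1
        runs = np.split(labels, boundaries)
        total += sum(1 for r in runs if r[0] != int(ExerciseClass.NO_EXERCISE))
    return total
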