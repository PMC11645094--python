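"""Synthetic multimodal exercise cohorts and the cohort file format.

Emulates a fatigue protocol in which participants perform sets of 10
repetitions of four lower-body exercises (Squat, Lunge Left, Lunge Right,
Plank Jump-in) while instrumented with a 4-load-cell balance board (30 Hz
vertical corner forces) and three IMUs (hip and both distal forearms, 3-axis
accelerometer + gyroscope at 60 Hz).  Group A performs one set per exercise
without fatigue; Group B repeats sets until exhaustion, with fatigue-related
signal drift injected parametrically via :class:`FatigueProfile`.

Each exercise has a deterministic template waveform (sums of low-frequency
harmonics with exercise-specific spectra); participants differ by random
amplitude/duration effects; the left lunge is the mediolateral mirror of the
right lunge.  All randomness is driven by per-repetition child seeds derived
from the master seed by stable hashing, so cohorts are fully reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

GRAVITY = 9.80665  # m/s^2
BOARD_RATE = 30.0  # Hz
IMU_RATE = 60.0  # Hz
EXERCISES = ("Squat", "LungeLeft", "LungeRight", "PlankJumpIn")
SENSORS = ("hip", "forearm_l", "forearm_r")
# base repetition duration in seconds
BASE_DURATION = {"Squat": 2.0, "LungeLeft": 2.0, "LungeRight": 2.0, "PlankJumpIn": 1.5}
# board sensor rectangle (anteroposterior depth x, mediolateral width y), metres
BOARD_DIMS = (0.238, 0.433)

# baseline measurement-noise standard deviations
ACC_NOISE_SD = 0.15  # m/s^2
GYRO_NOISE_SD = 0.05  # rad/s
FORCE_NOISE_SD = 5.0  # N
COP_SWAY_SD = 0.004  # m, baseline postural sway added to CoP


class FatigueProfile(BaseModel):
    """Parametric fatigue drift, per unit completion (fraction 0..1).

    An all-zero profile yields a statistically stationary generator (the null
    model).  Each field, varied alone, drives a monotone trend in one raw
    signal statistic.
    """

    amplitude_drift: float = 0.0  # fractional template-amplitude change
    noise_growth: float = 0.0  # multiplicative sensor-noise SD increase
    timing_jitter: float = 0.0  # SD of phase perturbation (fraction of rep)
    sway_growth: float = 0.0  # multiplicative CoP sway dispersion increase
    tremor_gain: float = 0.0  # 8-12 Hz accelerometer component, m/s^2 per unit

    @field_validator("amplitude_drift", "noise_growth", "timing_jitter",
                     "sway_growth", "tremor_gain")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("FatigueProfile fields must be >= 0")
        return v


#: default fatigued-cohort condition: fatigue primarily shifts the movement
#: pattern (amplitude drift dominates) with milder dispersion growth, so the
#: latent signature is cluster migration plus moderate spreading
DEFAULT_FATIGUE = FatigueProfile(
    amplitude_drift=0.5, noise_growth=0.3, timing_jitter=0.03,
    sway_growth=0.8, tremor_gain=0.2,
)


class ParticipantMeta(BaseModel):
    id: str
    group: str  # "A" or "B"
    mass: float  # kg
    height: float  # m
    sets_per_exercise: dict[str, int]
    random_effect: dict[str, float]  # amplitude, duration scaling factors

    @field_validator("mass", "height")
    @classmethod
    def _pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("mass and height must be > 0")
        return v

    @field_validator("group")
    @classmethod
    def _group(cls, v: str) -> str:
        if v not in ("A", "B"):
            raise ValueError("group must be 'A' or 'B'")
        return v

    def model_post_init(self, _ctx) -> None:
        for ex, s in self.sets_per_exercise.items():
            if self.group == "A" and s != 1:
                raise ValueError(f"group A participants perform 1 set ({ex}: {s})")
            if self.group == "B" and s < 2:
                raise ValueError(f"group B participants perform >= 2 sets ({ex}: {s})")


@dataclass
class RawRepetition:
    """One repetition's raw sensor streams plus metadata."""

    participant_id: str
    exercise: str
    set_index: int
    rep_index: int
    duration: float  # s
    board_forces: np.ndarray  # (T_board, 4) N: front_left, front_right, back_left, back_right
    imu_acc: dict[str, np.ndarray]  # sensor -> (T_imu, 3) m/s^2, sensor frame
    imu_gyro: dict[str, np.ndarray]  # sensor -> (T_imu, 3) rad/s, sensor frame
    tpose_acc: dict[str, np.ndarray]  # sensor -> (T, 3) static calibration window
    tpose_gyro: dict[str, np.ndarray]
    board_rate: float = BOARD_RATE
    imu_rate: float = IMU_RATE


class GeneratorConfig(BaseModel):
    """Cohort-level generator settings (the study conditions)."""

    n_group_a: int = 20
    n_group_b: int = 10
    reps_per_set: int = 10
    sets_range: tuple[int, int] = (5, 15)  # Group B sets drawn uniformly
    exercises: tuple[str, ...] = EXERCISES
    fatigue: FatigueProfile = Field(default_factory=lambda: DEFAULT_FATIGUE.model_copy())
    noise_scale: float = 1.0  # 0 disables measurement noise (testing)
    seed: int = 0

    @field_validator("n_group_a", "n_group_b")
    @classmethod
    def _ge0(cls, v: int) -> int:
        if v < 0:
            raise ValueError("group sizes must be >= 0")
        return v

    @field_validator("sets_range")
    @classmethod
    def _range(cls, v):
        if v[0] < 2 or v[1] < v[0]:
            raise ValueError("sets_range must satisfy 2 <= lo <= hi")
        return v

    @field_validator("exercises")
    @classmethod
    def _known(cls, v):
        for ex in v:
            if ex not in EXERCISES:
                raise ValueError(f"unknown exercise {ex!r}")
        return v


class CohortRecord(BaseModel):
    participant: str
    exercise: str
    set: int
    rep: int
    path: str
    tpose_path: str
    duration: float


class CohortManifest(BaseModel):
    schema_version: str = "1"
    master_seed: int = 0
    config: dict = Field(default_factory=dict)
    participants: list[ParticipantMeta] = Field(default_factory=list)
    records: list[CohortRecord] = Field(default_factory=list)

    def model_post_init(self, _ctx) -> None:
        keys = [(r.participant, r.exercise, r.set, r.rep) for r in self.records]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise ValueError(f"duplicate repetition key {dup}")


def child_seed(master: int, *key) -> int:
    """Stable per-item seed below 2^31 derived from the master seed and a key."""
    h = hashlib.blake2b("|".join(str(k) for k in (master,) + key).encode(),
                        digest_size=4).digest()
    return int.from_bytes(h, "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# exercise templates


def _harmonics(p: np.ndarray, terms: list[tuple[float, float, float]]) -> np.ndarray:
    """Sum of a_i * sin(2*pi*k_i*p + phi_i) over (a, k, phi) terms."""
    out = np.zeros_like(p)
    for a, k, phi in terms:
        out += a * np.sin(2 * np.pi * k * p + phi)
    return out


def exercise_template(exercise: str, p: np.ndarray) -> dict:
    """Noise-free template waveforms at phase ``p`` in [0, 1).

    Returns grf_fluct (dimensionless, around 0), cop (2, T) metres
    [anteroposterior, mediolateral], and per-sensor acc / gyro (3, T) arrays
    in the world frame (gravity excluded).  Axes: x anteroposterior,
    y mediolateral, z vertical.  The lunges share a nearly identical board
    signature (small mediolateral CoP) but differ strongly on the forearm
    IMUs, mirroring which arm swings.
    """
    if exercise == "Squat":
        grf = _harmonics(p, [(0.25, 1, -np.pi / 2), (0.10, 2, 0.0)])
        cop = np.vstack([0.040 * np.sin(2 * np.pi * p),
                         0.005 * np.sin(4 * np.pi * p)])
        acc = {
            "hip": np.vstack([_harmonics(p, [(0.4, 1, 0.0)]),
                              _harmonics(p, [(0.2, 2, 0.3)]),
                              _harmonics(p, [(1.6, 1, np.pi / 2), (0.4, 2, 0.0)])]),
            "forearm_l": np.vstack([_harmonics(p, [(0.5, 1, 0.2)]),
                                    _harmonics(p, [(0.2, 1, 1.0)]),
                                    _harmonics(p, [(0.9, 1, np.pi / 2)])]),
            "forearm_r": np.vstack([_harmonics(p, [(0.5, 1, 0.2)]),
                                    _harmonics(p, [(-0.2, 1, 1.0)]),
                                    _harmonics(p, [(0.9, 1, np.pi / 2)])]),
        }
        gyro = {
            "hip": np.vstack([_harmonics(p, [(0.15, 2, 0.0)]),
                              _harmonics(p, [(0.9, 1, 0.0)]),
                              _harmonics(p, [(0.1, 1, 0.5)])]),
            "forearm_l": np.vstack([_harmonics(p, [(0.3, 1, 0.0)]),
                                    _harmonics(p, [(0.5, 1, 0.7)]),
                                    _harmonics(p, [(0.2, 2, 0.0)])]),
            "forearm_r": np.vstack([_harmonics(p, [(-0.3, 1, 0.0)]),
                                    _harmonics(p, [(0.5, 1, 0.7)]),
                                    _harmonics(p, [(-0.2, 2, 0.0)])]),
        }
    elif exercise == "LungeRight":
        grf = _harmonics(p, [(0.20, 1, -np.pi / 2), (0.05, 3, 0.0)])
        cop = np.vstack([0.060 * np.sin(np.pi * p) ** 2,
                         0.003 * np.sin(2 * np.pi * p)])
        acc = {
            "hip": np.vstack([_harmonics(p, [(0.9, 1, 0.0), (0.3, 2, 0.4)]),
                              _harmonics(p, [(0.45, 1, 0.9)]),
                              _harmonics(p, [(1.1, 1, np.pi / 2)])]),
            "forearm_l": np.vstack([_harmonics(p, [(0.25, 1, 0.1)]),
                                    _harmonics(p, [(0.15, 1, 0.8)]),
                                    _harmonics(p, [(0.3, 1, 1.4)])]),
            "forearm_r": np.vstack([_harmonics(p, [(1.2, 1, 0.0), (0.3, 2, 0.2)]),
                                    _harmonics(p, [(0.7, 1, 0.5)]),
                                    _harmonics(p, [(0.9, 2, 0.0)])]),
        }
        gyro = {
            "hip": np.vstack([_harmonics(p, [(0.5, 1, 0.0)]),
                              _harmonics(p, [(0.6, 1, 0.4)]),
                              _harmonics(p, [(0.35, 1, 1.0)])]),
            "forearm_l": np.vstack([_harmonics(p, [(0.15, 1, 0.3)]),
                                    _harmonics(p, [(0.2, 1, 0.0)]),
                                    _harmonics(p, [(0.1, 2, 0.0)])]),
            "forearm_r": np.vstack([_harmonics(p, [(0.8, 1, 0.0)]),
                                    _harmonics(p, [(0.9, 1, 0.6), (0.3, 2, 0.0)]),
                                    _harmonics(p, [(0.5, 2, 0.3)])]),
        }
    elif exercise == "LungeLeft":
        return mirror_template(exercise_template("LungeRight", p))
    elif exercise == "PlankJumpIn":
        grf = _harmonics(p, [(0.45, 1, -np.pi / 2), (0.30, 2, 0.0), (0.15, 3, 0.4)])
        cop = np.vstack([0.050 * np.sin(2 * np.pi * p),
                         0.010 * np.sin(4 * np.pi * p + 0.7)])
        acc = {
            "hip": np.vstack([_harmonics(p, [(1.4, 2, 0.0), (0.5, 3, 0.3)]),
                              _harmonics(p, [(0.4, 2, 0.8)]),
                              _harmonics(p, [(2.2, 1, np.pi / 2), (0.8, 3, 0.0)])]),
            "forearm_l": np.vstack([_harmonics(p, [(0.8, 2, 0.1)]),
                                    _harmonics(p, [(0.3, 2, 0.9)]),
                                    _harmonics(p, [(1.1, 2, np.pi / 2)])]),
            "forearm_r": np.vstack([_harmonics(p, [(0.8, 2, 0.1)]),
                                    _harmonics(p, [(-0.3, 2, 0.9)]),
                                    _harmonics(p, [(1.1, 2, np.pi / 2)])]),
        }
        gyro = {
            "hip": np.vstack([_harmonics(p, [(0.3, 2, 0.0)]),
                              _harmonics(p, [(1.1, 2, 0.2)]),
                              _harmonics(p, [(0.2, 3, 0.0)])]),
            "forearm_l": np.vstack([_harmonics(p, [(0.4, 2, 0.0)]),
                                    _harmonics(p, [(0.6, 2, 0.5)]),
                                    _harmonics(p, [(0.3, 3, 0.1)])]),
            "forearm_r": np.vstack([_harmonics(p, [(-0.4, 2, 0.0)]),
                                    _harmonics(p, [(0.6, 2, 0.5)]),
                                    _harmonics(p, [(-0.3, 3, 0.1)])]),
        }
    else:
        raise ValueError(f"unknown exercise {exercise!r}")
    return {"grf": grf, "cop": cop, "acc": acc, "gyro": gyro}


def mirror_template(t: dict) -> dict:
    """Mediolateral mirror: negate y for vectors, x/z for angular rates, swap arms.

    Linear quantities (CoP, acceleration) flip their mediolateral (y)
    component; angular velocity is a pseudovector, so the components about
    the x and z axes flip instead; the two forearm sensors exchange roles.
    """
    swap = {"hip": "hip", "forearm_l": "forearm_r", "forearm_r": "forearm_l"}
    acc = {}
    gyro = {}
    for s in SENSORS:
        a = t["acc"][swap[s]].copy()
        a[1] *= -1.0
        acc[s] = a
        g = t["gyro"][swap[s]].copy()
        g[0] *= -1.0
        g[2] *= -1.0
        gyro[s] = g
    cop = t["cop"].copy()
    cop[1] *= -1.0
    return {"grf": t["grf"].copy(), "cop": cop, "acc": acc, "gyro": gyro}


# ---------------------------------------------------------------------------
# low-level signal assembly


def corner_forces(total: np.ndarray, cop_x: np.ndarray, cop_y: np.ndarray,
                  board_dims: tuple[float, float] = BOARD_DIMS) -> np.ndarray:
    """Distribute a total vertical force over the 4 corner cells.

    Corners at (+-a, +-b) with a = depth/2 (anteroposterior x, + front) and
    b = width/2 (mediolateral y, + right); the unique symmetric solution with
    the requested force moments is f = F/4 * (1 +- x/a +- y/b).
    Column order: front_left, front_right, back_left, back_right.
    """
    a, b = board_dims[0] / 2.0, board_dims[1] / 2.0
    xa = np.clip(cop_x / a, -1, 1)
    yb = np.clip(cop_y / b, -1, 1)
    f = np.stack([
        total / 4 * (1 + xa - yb),
        total / 4 * (1 + xa + yb),
        total / 4 * (1 - xa - yb),
        total / 4 * (1 - xa + yb),
    ], axis=1)
    return np.clip(f, 0.0, None)


def _session_rotation(rng: np.random.Generator, max_angle_deg: float = 15.0) -> np.ndarray:
    """Small random sensor-mounting misalignment (rotation matrix)."""
    from scipy.spatial.transform import Rotation

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
    return Rotation.from_rotvec(angle * axis).as_matrix()


def session_tpose(rotations: dict[str, np.ndarray], rng: np.random.Generator,
                  duration: float = 1.0, noise_scale: float = 1.0) -> tuple[dict, dict]:
    """Static T-pose calibration window in each sensor's frame."""
    n = int(round(duration * IMU_RATE))
    g_world = np.array([0.0, 0.0, GRAVITY])
    acc, gyro = {}, {}
    for s in SENSORS:
        measured = rotations[s].T @ g_world  # sensor-frame gravity reaction
        acc[s] = measured[None, :] + noise_scale * 0.3 * ACC_NOISE_SD * rng.normal(size=(n, 3))
        gyro[s] = noise_scale * 0.3 * GYRO_NOISE_SD * rng.normal(size=(n, 3))
    return acc, gyro


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, fs: float,
                  cutoff: float = 1.5) -> np.ndarray:
    """Low-frequency (postural-sway-like) noise with standard deviation sd."""
    from scipy.ndimage import gaussian_filter1d

    sigma = fs / (2 * np.pi * cutoff)
    x = gaussian_filter1d(rng.normal(size=n), sigma, mode="wrap")
    s = x.std()
    return sd * x / s if s > 0 else np.zeros(n)


def generate_repetition(participant: ParticipantMeta, exercise: str,
                        fatigue_fraction: float, seed: int,
                        profile: FatigueProfile | None = None,
                        noise_scale: float = 1.0,
                        set_index: int = 0, rep_index: int = 0,
                        rotations: dict[str, np.ndarray] | None = None,
                        tpose: tuple[dict, dict] | None = None) -> RawRepetition:
    """Generate one repetition at the given fatigue fraction in [0, 1]."""
    if exercise not in EXERCISES:
        raise ValueError(f"unknown exercise {exercise!r}")
    if not 0.0 <= fatigue_fraction <= 1.0:
        raise ValueError("fatigue_fraction must be in [0, 1]")
    profile = profile if profile is not None else FatigueProfile()
    phi = fatigue_fraction
    rng = np.random.default_rng(seed)

    duration = BASE_DURATION[exercise] * participant.random_effect.get("duration", 1.0)
    n_imu = int(round(duration * IMU_RATE))
    n_board = int(round(duration * BOARD_RATE))
    amp = participant.random_effect.get("amplitude", 1.0) * (1.0 + profile.amplitude_drift * phi)
    noise = noise_scale * (1.0 + profile.noise_growth * phi)

    jitter = rng.normal(0.0, profile.timing_jitter * phi) if profile.timing_jitter * phi > 0 else 0.0
    p_imu = (np.arange(n_imu) / (duration * IMU_RATE) + jitter) % 1.0
    p_board = (np.arange(n_board) / (duration * BOARD_RATE) + jitter) % 1.0

    tpl_imu = exercise_template(exercise, p_imu)
    tpl_board = exercise_template(exercise, p_board)

    if rotations is None:
        rot_rng = np.random.default_rng(child_seed(seed, "rot"))
        rotations = {s: _session_rotation(rot_rng) for s in SENSORS}
    if tpose is None:
        tpose = session_tpose(rotations, np.random.default_rng(child_seed(seed, "tpose")),
                              noise_scale=noise_scale)

    t_imu = np.arange(n_imu) / IMU_RATE
    tremor_amp = profile.tremor_gain * phi
    g_world = np.array([0.0, 0.0, GRAVITY])
    imu_acc, imu_gyro = {}, {}
    for s in SENSORS:
        acc_world = amp * tpl_imu["acc"][s].T  # (T, 3)
        if tremor_amp > 0:
            f_trem = rng.uniform(8.0, 12.0)
            ph = rng.uniform(0, 2 * np.pi, size=3)
            acc_world = acc_world + tremor_amp * np.sin(
                2 * np.pi * f_trem * t_imu[:, None] + ph[None, :])
        acc_world = acc_world + g_world[None, :]
        gyro_world = amp * tpl_imu["gyro"][s].T
        # rotate into the (misaligned) sensor frame, then add measurement noise
        imu_acc[s] = acc_world @ rotations[s] + noise * ACC_NOISE_SD * rng.normal(size=(n_imu, 3))
        imu_gyro[s] = gyro_world @ rotations[s] + noise * GYRO_NOISE_SD * rng.normal(size=(n_imu, 3))

    total = participant.mass * GRAVITY * (1.0 + amp * tpl_board["grf"])
    total = total + noise * FORCE_NOISE_SD * rng.normal(size=n_board)
    sway_sd = noise_scale * COP_SWAY_SD * (1.0 + profile.sway_growth * phi)
    cop_x = amp * tpl_board["cop"][0] + _smooth_noise(rng, n_board, sway_sd, BOARD_RATE)
    cop_y = amp * tpl_board["cop"][1] + _smooth_noise(rng, n_board, sway_sd, BOARD_RATE)
    board = corner_forces(np.clip(total, 0.0, None), cop_x, cop_y)

    return RawRepetition(
        participant_id=participant.id, exercise=exercise, set_index=set_index,
        rep_index=rep_index, duration=duration, board_forces=board,
        imu_acc=imu_acc, imu_gyro=imu_gyro,
        tpose_acc=tpose[0], tpose_gyro=tpose[1],
    )


def generate_static_stance(participant: ParticipantMeta, duration: float, seed: int,
                           noise_scale: float = 1.0) -> np.ndarray:
    """Quiet-standing corner forces (T, 4); mean total ~ mass * g."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * BOARD_RATE))
    total = participant.mass * GRAVITY + noise_scale * FORCE_NOISE_SD * rng.normal(size=n)
    cop_x = _smooth_noise(rng, n, noise_scale * COP_SWAY_SD, BOARD_RATE)
    cop_y = _smooth_noise(rng, n, noise_scale * COP_SWAY_SD, BOARD_RATE)
    return corner_forces(total, cop_x, cop_y)


# ---------------------------------------------------------------------------
# cohort generation


def _make_participant(pid: str, group: str, config: GeneratorConfig) -> ParticipantMeta:
    rng = np.random.default_rng(child_seed(config.seed, "participant", pid))
    # anthropometrics reflect the two recruited groups (means +- SD)
    if group == "A":
        mass = float(np.clip(rng.normal(66.6, 9.1), 45, 110))
        height = float(np.clip(rng.normal(1.739, 0.07), 1.5, 2.05))
        sets = {ex: 1 for ex in config.exercises}
    else:
        mass = float(np.clip(rng.normal(68.2, 13.3), 45, 120))
        height = float(np.clip(rng.normal(1.755, 0.07), 1.5, 2.05))
        lo, hi = config.sets_range
        sets = {ex: int(rng.integers(lo, hi + 1)) for ex in config.exercises}
    effect = {
        "amplitude": float(np.clip(rng.normal(1.0, 0.08), 0.75, 1.25)),
        "duration": float(np.clip(rng.normal(1.0, 0.07), 0.8, 1.2)),
    }
    return ParticipantMeta(id=pid, group=group, mass=mass, height=height,
                           sets_per_exercise=sets, random_effect=effect)


def fatigue_fraction_for_set(set_index: int, total_sets: int) -> float:
    """Set i of S maps to i/(S-1); a single set (Group A) maps to 0."""
    if total_sets <= 1:
        return 0.0
    return set_index / (total_sets - 1)


def generate_cohort(config: GeneratorConfig) -> tuple[CohortManifest, dict]:
    """Generate a full cohort in memory.

    Returns the manifest (paths filled relative to a future cohort directory)
    and a dict mapping (participant, exercise, set, rep) to RawRepetition.
    """
    participants = (
        [_make_participant(f"A{i:02d}", "A", config) for i in range(config.n_group_a)]
        + [_make_participant(f"B{i:02d}", "B", config) for i in range(config.n_group_b)]
    )
    reps: dict[tuple, RawRepetition] = {}
    records: list[CohortRecord] = []
    for part in participants:
        for ex in config.exercises:
            n_sets = part.sets_per_exercise[ex]
            sess_rng = np.random.default_rng(child_seed(config.seed, "session", part.id, ex))
            rotations = {s: _session_rotation(sess_rng) for s in SENSORS}
            tpose = session_tpose(rotations, sess_rng, noise_scale=config.noise_scale)
            profile = config.fatigue if part.group == "B" else FatigueProfile()
            for si in range(n_sets):
                phi = fatigue_fraction_for_set(si, n_sets) if part.group == "B" else 0.0
                for ri in range(config.reps_per_set):
                    seed = child_seed(config.seed, part.id, ex, si, ri)
                    rep = generate_repetition(
                        part, ex, phi, seed, profile=profile,
                        noise_scale=config.noise_scale, set_index=si, rep_index=ri,
                        rotations=rotations, tpose=tpose,
                    )
                    reps[(part.id, ex, si, ri)] = rep
                    records.append(CohortRecord(
                        participant=part.id, exercise=ex, set=si, rep=ri,
                        path=f"data/{part.id}/{ex}/set{si}_rep{ri}.csv",
                        tpose_path=f"data/{part.id}/{ex}/tpose.csv",
                        duration=rep.duration,
                    ))
    manifest = CohortManifest(master_seed=config.seed,
                              config=json.loads(config.model_dump_json()),
                              participants=participants, records=records)
    return manifest, reps


def concatenate_repetitions(reps: list[RawRepetition], seed: int,
                            gap_range: tuple[float, float] = (1.0, 2.0),
                            noise_scale: float = 1.0) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Join repetitions' hip world-acceleration magnitude into one stream.

    Returns the 60 Hz dynamic-acceleration magnitude stream (quiet gaps of
    gap_range seconds between repetitions) and the ground-truth half-open
    sample intervals of each repetition.  Used to exercise segmentation.
    """
    rng = np.random.default_rng(seed)
    chunks: list[np.ndarray] = []
    truth: list[tuple[int, int]] = []
    pos = 0

    def quiet(dur: float) -> np.ndarray:
        n = int(round(dur * IMU_RATE))
        return noise_scale * ACC_NOISE_SD * rng.normal(size=n)

    g0 = quiet(rng.uniform(*gap_range))
    chunks.append(np.abs(g0))
    pos += len(g0)
    for rep in reps:
        tpl = exercise_template(rep.exercise,
                                np.arange(len(rep.imu_acc["hip"])) / (rep.duration * IMU_RATE))
        mag = np.linalg.norm(tpl["acc"]["hip"], axis=0)
        mag = mag + noise_scale * ACC_NOISE_SD * rng.normal(size=len(mag))
        chunks.append(np.abs(mag))
        truth.append((pos, pos + len(mag)))
        pos += len(mag)
        g = np.abs(quiet(rng.uniform(*gap_range)))
        chunks.append(g)
        pos += len(g)
    return np.concatenate(chunks), truth


# ---------------------------------------------------------------------------
# cohort file I/O

_BOARD_COLS = ["force_front_left_N", "force_front_right_N",
               "force_back_left_N", "force_back_right_N"]


def _imu_cols() -> list[str]:
    cols = []
    for s in SENSORS:
        cols += [f"{s}_acc_{ax}_mps2" for ax in "xyz"]
        cols += [f"{s}_gyro_{ax}_radps" for ax in "xyz"]
    return cols


def _rep_frame(rep: RawRepetition) -> pd.DataFrame:
    n_b, n_i = len(rep.board_forces), len(next(iter(rep.imu_acc.values())))
    n = max(n_b, n_i)
    data: dict[str, np.ndarray] = {}
    pad = lambda a, m: np.concatenate([a, np.full(m - len(a), np.nan)])
    data["t_board_s"] = pad(np.arange(n_b) / rep.board_rate, n)
    for j, c in enumerate(_BOARD_COLS):
        data[c] = pad(rep.board_forces[:, j], n)
    data["t_imu_s"] = pad(np.arange(n_i) / rep.imu_rate, n)
    for s in SENSORS:
        for j, ax in enumerate("xyz"):
            data[f"{s}_acc_{ax}_mps2"] = pad(rep.imu_acc[s][:, j], n)
        for j, ax in enumerate("xyz"):
            data[f"{s}_gyro_{ax}_radps"] = pad(rep.imu_gyro[s][:, j], n)
    return pd.DataFrame(data)


def write_cohort(manifest: CohortManifest, reps: dict, directory: str | Path) -> None:
    """Write manifest.json plus one CSV per repetition (and per-session T-pose)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "manifest.json").write_text(manifest.model_dump_json(indent=1))
    tpose_written = set()
    for rec in manifest.records:
        rep = reps[(rec.participant, rec.exercise, rec.set, rec.rep)]
        path = directory / rec.path
        path.parent.mkdir(parents=True, exist_ok=True)
        _rep_frame(rep).to_csv(path, index=False, float_format="%.17g")
        if rec.tpose_path not in tpose_written:
            n = len(next(iter(rep.tpose_acc.values())))
            data = {"t_imu_s": np.arange(n) / rep.imu_rate}
            for s in SENSORS:
                for j, ax in enumerate("xyz"):
                    data[f"{s}_acc_{ax}_mps2"] = rep.tpose_acc[s][:, j]
                for j, ax in enumerate("xyz"):
                    data[f"{s}_gyro_{ax}_radps"] = rep.tpose_gyro[s][:, j]
            pd.DataFrame(data).to_csv(directory / rec.tpose_path, index=False,
                                      float_format="%.17g")
            tpose_written.add(rec.tpose_path)


class CohortReadError(Exception):
    pass


class MissingFileError(CohortReadError):
    pass


class SchemaError(CohortReadError):
    pass


class RateMismatchError(CohortReadError):
    pass


class Cohort:
    """Lazy reader over a cohort directory written by :func:`write_cohort`."""

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        mpath = self.directory / "manifest.json"
        if not mpath.exists():
            raise MissingFileError(f"missing manifest.json in {self.directory}")
        try:
            self.manifest = CohortManifest.model_validate_json(mpath.read_text())
        except ValueError as e:
            raise SchemaError(str(e)) from e
        self._index = {(r.participant, r.exercise, r.set, r.rep): r
                       for r in self.manifest.records}
        self.participants = {p.id: p for p in self.manifest.participants}
        for key, rec in self._index.items():
            if not (self.directory / rec.path).exists():
                raise MissingFileError(f"missing file for key {key}: {rec.path}")
        self._tpose_cache: dict[str, tuple[dict, dict]] = {}

    def keys(self) -> list[tuple]:
        return list(self._index)

    def _read_tpose(self, tpose_path: str) -> tuple[dict, dict]:
        if tpose_path not in self._tpose_cache:
            df = pd.read_csv(self.directory / tpose_path, float_precision="round_trip")
            acc = {s: df[[f"{s}_acc_{ax}_mps2" for ax in "xyz"]].to_numpy()
                   for s in SENSORS}
            gyro = {s: df[[f"{s}_gyro_{ax}_radps" for ax in "xyz"]].to_numpy()
                    for s in SENSORS}
            self._tpose_cache[tpose_path] = (acc, gyro)
        return self._tpose_cache[tpose_path]

    def get(self, participant: str, exercise: str, set_index: int, rep_index: int) -> RawRepetition:
        key = (participant, exercise, set_index, rep_index)
        if key not in self._index:
            raise KeyError(f"no such repetition {key}")
        rec = self._index[key]
        df = pd.read_csv(self.directory / rec.path, float_precision="round_trip")
        expected = ["t_board_s"] + _BOARD_COLS + ["t_imu_s"] + _imu_cols()
        if list(df.columns) != expected:
            raise SchemaError(f"unexpected columns in {rec.path}")
        board = df[_BOARD_COLS].dropna().to_numpy()
        t_board = df["t_board_s"].dropna().to_numpy()
        t_imu = df["t_imu_s"].dropna().to_numpy()
        if len(t_board) > 1:
            rate_b = 1.0 / np.median(np.diff(t_board))
            if abs(rate_b - BOARD_RATE) > 0.5:
                raise RateMismatchError(
                    f"board rate {rate_b:.1f} Hz != {BOARD_RATE} Hz in {rec.path}")
        if len(t_imu) > 1:
            rate_i = 1.0 / np.median(np.diff(t_imu))
            if abs(rate_i - IMU_RATE) > 0.5:
                raise RateMismatchError(
                    f"imu rate {rate_i:.1f} Hz != {IMU_RATE} Hz in {rec.path}")
        n_imu = len(t_imu)
        acc = {s: df[[f"{s}_acc_{ax}_mps2" for ax in "xyz"]].to_numpy()[:n_imu]
               for s in SENSORS}
        gyro = {s: df[[f"{s}_gyro_{ax}_radps" for ax in "xyz"]].to_numpy()[:n_imu]
                for s in SENSORS}
        tpose_acc, tpose_gyro = self._read_tpose(rec.tpose_path)
        return RawRepetition(
            participant_id=participant, exercise=exercise, set_index=set_index,
            rep_index=rep_index, duration=rec.duration, board_forces=board,
            imu_acc=acc, imu_gyro=gyro, tpose_acc=tpose_acc, tpose_gyro=tpose_gyro,
        )


def read_cohort(directory: str | Path) -> Cohort:
    return Cohort(directory)


class InMemoryCohort:
    """Cohort-compatible view over generate_cohort output (no disk round-trip)."""

    def __init__(self, manifest: CohortManifest, reps: dict):
        self.manifest = manifest
        self._reps = reps
        self.participants = {p.id: p for p in manifest.participants}

    def keys(self) -> list[tuple]:
        return list(self._reps)

    def get(self, participant: str, exercise: str, set_index: int,
            rep_index: int) -> RawRepetition:
        return self._reps[(participant, exercise, set_index, rep_index)]
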