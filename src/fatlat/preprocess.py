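"""Raw sensor streams -> standardized fixed-length repetition matrices.

Pipeline order (each stage pure): T-pose calibration -> gravity removal and
height normalization -> GRF/CoP derivation -> 15 Hz zero-phase low-pass ->
segmentation (when streams arrive concatenated) -> cubic-spline resampling to
192 frames -> per-type standardization.  The output of the pipeline is an
``(192, n)`` matrix per repetition with a 4-class one-hot activity label,
where ``n`` depends on the sensor-combination database variant:

========  =========================================  ===
variant   channels                                    n
========  =========================================  ===
DB0       balance board (GRF, CoP x/y)                 3
DB1       DB0 + hip IMU (acc + gyro)                   9
DB2       DB0 + hip and both forearm IMUs             21
DB3       hip IMU only                                 6
DB4       hip + both forearm IMUs                     18
========  =========================================  ===

Standardization statistics are a scalar mean/SD per signal type (GRF, CoP,
acceleration, angular velocity) pooled over all channels of that type, and
are computed only from the training split of Group A for a given fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator, TransformerMixin

from .synthio import (BOARD_DIMS, BOARD_RATE, EXERCISES, GRAVITY, IMU_RATE,
                      SENSORS, Cohort, RawRepetition)

N_FRAMES = 192
FILTER_CUTOFF_HZ = 15.0
FILTER_ORDER = 4

DATABASES = ("DB0", "DB1", "DB2", "DB3", "DB4")


def db_channels(database_id: str) -> list[tuple[str, str]]:
    """Ordered (channel name, signal type) pairs for a database variant."""
    board = [("grf_norm", "grf"), ("cop_x", "cop"), ("cop_y", "cop")]

    def imu(sensor: str) -> list[tuple[str, str]]:
        return ([(f"{sensor}_acc_{ax}", "acc") for ax in "xyz"]
                + [(f"{sensor}_gyro_{ax}", "gyro") for ax in "xyz"])

    if database_id == "DB0":
        return board
    if database_id == "DB1":
        return board + imu("hip")
    if database_id == "DB2":
        return board + [c for s in SENSORS for c in imu(s)]
    if database_id == "DB3":
        return imu("hip")
    if database_id == "DB4":
        return [c for s in SENSORS for c in imu(s)]
    raise ValueError(f"unknown database variant {database_id!r}")


@dataclass
class ProcessedRepetition:
    """One repetition as a standardized (192, n) matrix with one-hot label."""

    X: np.ndarray  # (192, n)
    y: np.ndarray  # (4,) one-hot, class order = EXERCISES
    participant_id: str
    exercise: str
    set_index: int
    rep_index: int
    database_id: str


class UnloadedBoardError(ValueError):
    pass


class CalibrationError(ValueError):
    pass


def derive_grf_cop(board_forces: np.ndarray, mass: float,
                   board_dims: tuple[float, float] = BOARD_DIMS,
                   force_floor: float = 50.0,
                   max_unloaded_fraction: float = 0.3) -> np.ndarray:
    """Mass-normalized GRF and initial-subtracted CoP from 4 corner forces.

    Input columns: front_left, front_right, back_left, back_right (N), with
    corners at (+-a, +-b), a = anteroposterior half-depth, b = mediolateral
    half-width.  Returns (T, 3): GRF/mass (N/kg), CoP x and y (m) with the
    first-frame CoP subtracted so CoP(0) = (0, 0) exactly.

    Brief unloaded stretches (flight phases of jumping exercises) are
    tolerated up to ``max_unloaded_fraction``; CoP is interpolated across
    them since it is undefined without ground contact.
    """
    if mass <= 0:
        raise ValueError("mass must be > 0")
    f = np.asarray(board_forces, dtype=float)
    total = f.sum(axis=1)
    unloaded = total < force_floor
    if unloaded.mean() > max_unloaded_fraction:
        raise UnloadedBoardError(
            f"board unloaded (total force < {force_floor} N) on "
            f"{unloaded.mean():.0%} of frames")
    a, b = board_dims[0] / 2.0, board_dims[1] / 2.0
    safe_total = np.where(unloaded, np.nan, total)
    cop_x = a * (f[:, 0] + f[:, 1] - f[:, 2] - f[:, 3]) / safe_total
    cop_y = b * (-f[:, 0] + f[:, 1] - f[:, 2] + f[:, 3]) / safe_total
    # interpolate CoP over briefly unloaded frames
    if unloaded.any():
        idx = np.arange(len(total))
        cop_x = np.interp(idx, idx[~unloaded], cop_x[~unloaded])
        cop_y = np.interp(idx, idx[~unloaded], cop_y[~unloaded])
    cop_x = cop_x - cop_x[0]
    cop_y = cop_y - cop_y[0]
    return np.stack([total / mass, cop_x, cop_y], axis=1)


def estimate_tpose_rotation(tpose_acc: np.ndarray, tpose_gyro: np.ndarray,
                            rate: float = IMU_RATE,
                            gyro_threshold: float = 0.2,
                            min_duration: float = 0.5) -> np.ndarray:
    """Sensor-to-world rotation from a static T-pose window.

    During the T-pose all segments are assumed world-aligned, so the mean
    accelerometer reading must be the gravity reaction (0, 0, +g) once
    rotated to the world frame.  Gravity fixes the rotation only up to yaw;
    the minimal rotation aligning measured gravity with the world vertical
    is returned (3x3 matrix, right-multiplied onto row vectors' transpose:
    world = R @ sensor).
    """
    acc = np.asarray(tpose_acc, dtype=float)
    gyro = np.asarray(tpose_gyro, dtype=float)
    if len(acc) < min_duration * rate:
        raise CalibrationError(
            f"T-pose window shorter than {min_duration} s at {rate} Hz")
    gyro_norm = float(np.linalg.norm(gyro.mean(axis=0)) + np.linalg.norm(gyro, axis=1).mean())
    if gyro_norm > 2 * gyro_threshold:
        raise CalibrationError(
            f"non-static T-pose window (gyro activity {gyro_norm:.3f} rad/s)")
    mean_acc = acc.mean(axis=0)
    if np.linalg.norm(mean_acc) < 0.5 * GRAVITY:
        raise CalibrationError("T-pose accelerometer mean far from gravity magnitude")
    rot, _ = Rotation.align_vectors([[0.0, 0.0, GRAVITY]], [mean_acc])
    return rot.as_matrix()


def apply_calibration(stream: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Rotate a (T, 3) sensor-frame stream into the world frame."""
    return np.asarray(stream, dtype=float) @ np.asarray(rotation).T


def remove_gravity_normalize(world_acc: np.ndarray, height: float) -> np.ndarray:
    """Subtract the constant gravity reaction and divide by participant height."""
    if height <= 0:
        raise ValueError("height must be > 0")
    out = np.asarray(world_acc, dtype=float).copy()
    out[:, 2] -= GRAVITY
    return out / height


def lowpass_filter(signal: np.ndarray, fs: float,
                   cutoff: float = FILTER_CUTOFF_HZ,
                   order: int = FILTER_ORDER) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    Applied along axis 0; DC gain is exactly 1.  The effective magnitude
    response is the squared single-pass Butterworth response, i.e. 0.5 at
    the cutoff frequency.
    """
    signal = np.asarray(signal, dtype=float)
    if fs <= 2 * cutoff:
        raise ValueError(
            f"sampling rate {fs} Hz must exceed twice the cutoff {cutoff} Hz")
    b, a = butter(order, cutoff / (fs / 2.0), btype="low")
    padlen = 3 * (max(len(a), len(b)) - 1)
    if signal.shape[0] <= padlen:
        raise ValueError(
            f"signal length {signal.shape[0]} too short for zero-phase "
            f"filtering (needs > {padlen} samples)")
    return filtfilt(b, a, signal, axis=0)


def segment_repetitions(acc_magnitude: np.ndarray, fs: float = IMU_RATE,
                        threshold: float = 0.3,
                        min_quiet_gap: float = 0.5,
                        min_duration: float = 0.5,
                        smooth_window: float = 0.1) -> list[tuple[int, int]]:
    """Movement intervals from a gravity-free acceleration-magnitude stream.

    Thresholds a moving-average envelope, merges bursts separated by less
    than ``min_quiet_gap`` seconds, and drops bursts shorter than
    ``min_duration``.  Returns sorted, non-overlapping half-open [start, end)
    sample intervals; an all-quiet stream yields an empty list.
    """
    x = np.abs(np.asarray(acc_magnitude, dtype=float))
    w = max(1, int(round(smooth_window * fs)))
    kernel = np.ones(w) / w
    env = np.convolve(x, kernel, mode="same")
    active = env > threshold
    if not active.any():
        return []
    runs = []
    i = 0
    n = len(active)
    while i < n:
        if active[i]:
            j = i
            while j < n and active[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    # merge runs separated by less than the minimum quiet gap
    gap = int(round(min_quiet_gap * fs))
    merged = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_len = int(round(min_duration * fs))
    return [(s, e) for s, e in merged if e - s >= min_len]


def resample_to_frames(t: np.ndarray, x: np.ndarray,
                       n_frames: int = N_FRAMES) -> np.ndarray:
    """Cubic-spline resampling of (T,) or (T, C) samples onto a uniform grid.

    The grid spans [t[0], t[-1]] inclusively, so the first and last samples
    are preserved exactly.  Requires at least 4 samples.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(t) < 4:
        raise ValueError("cubic spline resampling requires >= 4 samples")
    grid = np.linspace(t[0], t[-1], n_frames)
    return CubicSpline(t, x, axis=0)(grid)


# ---------------------------------------------------------------------------
# standardization


class TypeStandardizer(BaseEstimator, TransformerMixin):
    """Per-signal-type z-scoring with statistics pooled over the training set.

    Parameters
    ----------
    channel_types : list of str
        Signal type of each channel, in column order of the matrices
        ("grf", "cop", "acc" or "gyro").

    Attributes
    ----------
    stats_ : dict
        type -> (mean, sd), scalars pooled over every frame and channel of
        that type in the fitted data.
    """

    def __init__(self, channel_types: list[str] | None = None):
        self.channel_types = channel_types

    def fit(self, X: np.ndarray, y=None) -> "TypeStandardizer":
        X = np.asarray(X, dtype=float)  # (R, frames, channels)
        types = np.asarray(self.channel_types)
        if X.ndim != 3 or X.shape[2] != len(types):
            raise ValueError("X must be (reps, frames, channels) matching channel_types")
        self.stats_ = {}
        for t in dict.fromkeys(self.channel_types):
            vals = X[:, :, types == t].ravel()
            mu, sd = float(vals.mean()), float(vals.std())
            if sd <= 0:
                raise ValueError(f"degenerate signal type {t!r}: zero variance")
            self.stats_[t] = (mu, sd)
        return self

    def _mu_sd(self) -> tuple[np.ndarray, np.ndarray]:
        mu = np.array([self.stats_[t][0] for t in self.channel_types])
        sd = np.array([self.stats_[t][1] for t in self.channel_types])
        return mu, sd

    def transform(self, X: np.ndarray) -> np.ndarray:
        mu, sd = self._mu_sd()
        return (np.asarray(X, dtype=float) - mu) / sd

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        mu, sd = self._mu_sd()
        return np.asarray(X, dtype=float) * sd + mu

    # -- JSON persistence (per-fold provenance) ---------------------------
    def to_json(self, fold: int | None = None,
                training_subjects: list[str] | None = None) -> str:
        return json.dumps({
            "channel_types": list(self.channel_types),
            "stats": {t: {"mean": m, "sd": s} for t, (m, s) in self.stats_.items()},
            "fold": fold,
            "training_subjects": training_subjects,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TypeStandardizer":
        d = json.loads(text)
        obj = cls(channel_types=d["channel_types"])
        obj.stats_ = {t: (v["mean"], v["sd"]) for t, v in d["stats"].items()}
        obj.fold = d.get("fold")
        obj.training_subjects = d.get("training_subjects")
        return obj


def compute_standardization(X: np.ndarray, channel_types: list[str]) -> TypeStandardizer:
    """Fit per-type statistics on Group-A training repetitions (R, 192, n)."""
    return TypeStandardizer(channel_types=channel_types).fit(X)


def standardize(X: np.ndarray, stats: TypeStandardizer) -> np.ndarray:
    return stats.transform(X)


# ---------------------------------------------------------------------------
# full pipeline


def _maybe_filter(x: np.ndarray, fs: float) -> np.ndarray:
    # board channels sample at 30 Hz where a 15 Hz cutoff sits on Nyquist;
    # the filter is skipped there (it would be the identity in the passband)
    if fs > 2 * FILTER_CUTOFF_HZ:
        return lowpass_filter(x, fs)
    return x


def process_repetition(rep: RawRepetition, mass: float, height: float,
                       database_id: str,
                       rotations: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """Run the fixed pipeline on one repetition; returns the (192, n) matrix."""
    channels = db_channels(database_id)
    needs_board = any(t in ("grf", "cop") for _, t in channels)
    needs_imu = any(t in ("acc", "gyro") for _, t in channels)
    cols: dict[str, np.ndarray] = {}

    if needs_board:
        grf_cop = derive_grf_cop(rep.board_forces, mass)
        grf_cop = _maybe_filter(grf_cop, rep.board_rate)
        # re-anchor CoP after filtering so the initial-subtraction contract holds
        grf_cop[:, 1] -= grf_cop[0, 1]
        grf_cop[:, 2] -= grf_cop[0, 2]
        t_board = np.arange(len(grf_cop)) / rep.board_rate
        rs = resample_to_frames(t_board, grf_cop)
        cols["grf_norm"], cols["cop_x"], cols["cop_y"] = rs[:, 0], rs[:, 1], rs[:, 2]

    if needs_imu:
        if rotations is None:
            rotations = {s: estimate_tpose_rotation(rep.tpose_acc[s], rep.tpose_gyro[s],
                                                    rate=rep.imu_rate)
                         for s in SENSORS}
        t_imu = None
        for s in SENSORS:
            if not any(name.startswith(s) for name, _ in channels):
                continue
            acc_w = apply_calibration(rep.imu_acc[s], rotations[s])
            acc_n = remove_gravity_normalize(acc_w, height)
            gyro_w = apply_calibration(rep.imu_gyro[s], rotations[s])
            acc_f = _maybe_filter(acc_n, rep.imu_rate)
            gyro_f = _maybe_filter(gyro_w, rep.imu_rate)
            t_imu = np.arange(len(acc_f)) / rep.imu_rate
            acc_rs = resample_to_frames(t_imu, acc_f)
            gyro_rs = resample_to_frames(t_imu, gyro_f)
            for j, ax in enumerate("xyz"):
                cols[f"{s}_acc_{ax}"] = acc_rs[:, j]
                cols[f"{s}_gyro_{ax}"] = gyro_rs[:, j]

    return np.stack([cols[name] for name, _ in channels], axis=1)


def one_hot(exercise: str) -> np.ndarray:
    y = np.zeros(len(EXERCISES))
    y[EXERCISES.index(exercise)] = 1.0
    return y


def assemble_dataset(cohort: Cohort, database_id: str,
                     stats: TypeStandardizer | None = None,
                     participants: list[str] | None = None) -> list[ProcessedRepetition]:
    """Process every repetition of the selected participants for one variant.

    When ``stats`` is given, matrices are standardized with it (per-type
    z-scoring with fold-training statistics); otherwise raw pipeline output
    is returned (as used to *compute* the statistics).
    """
    channels = db_channels(database_id)
    out: list[ProcessedRepetition] = []
    rot_cache: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for (pid, ex, si, ri) in cohort.keys():
        if participants is not None and pid not in participants:
            continue
        rep = cohort.get(pid, ex, si, ri)
        meta = cohort.participants[pid]
        skey = (pid, ex)
        if skey not in rot_cache:
            rot_cache[skey] = {s: estimate_tpose_rotation(rep.tpose_acc[s],
                                                          rep.tpose_gyro[s],
                                                          rate=rep.imu_rate)
                               for s in SENSORS}
        X = process_repetition(rep, meta.mass, meta.height, database_id,
                               rotations=rot_cache[skey])
        if stats is not None:
            X = stats.transform(X)
        out.append(ProcessedRepetition(X=X, y=one_hot(ex), participant_id=pid,
                                       exercise=ex, set_index=si, rep_index=ri,
                                       database_id=database_id))
    if not out:
        return out
    n_expected = len(channels)
    if out[0].X.shape != (N_FRAMES, n_expected):
        raise ValueError(f"pipeline produced {out[0].X.shape}, expected "
                         f"({N_FRAMES}, {n_expected}) for {database_id}")
    return out


def dataset_arrays(dataset: list[ProcessedRepetition]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a processed dataset into (R, 192, n) matrices and (R,) labels."""
    X = np.stack([d.X for d in dataset])
    y = np.array([int(np.argmax(d.y)) for d in dataset])
    return X, y
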