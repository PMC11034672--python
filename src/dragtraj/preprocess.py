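"""Canonical rotation, length filtering, standardization, padding, labels.

Every trajectory is rotated clockwise about the screen origin by the angle
of its endpoint, so that after rotation the endpoint lies on the positive
x-axis. This removes target-direction variance: trajectories aimed at any
of the 8 targets become directly comparable. Rotation is an isometry, so
all inter-point distances (and hence speeds and accelerations) are
unchanged.

Sequences retained for modelling have 20-69 points (inclusive); shorter or
longer drags are discarded. Features are standardized to zero mean and unit
variance over the *unpadded* timesteps of the fitting set, then zero-padded
to a fixed 69 timesteps so the classifier sees fixed-shape input (all-zero
padding rows are masked downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import Trajectory, TrajectoryDataset

TARGET_LEN = 69
MIN_LEN = 20
MAX_LEN = 69
PAD_VALUE = 0.0

_LABELS = {"TD": (1.0, 0.0), "ASD": (0.0, 1.0)}


@dataclass
class RotationAngle:
    """Endpoint angle in degrees, wrapped into [0, 360)."""

    theta_deg: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_deg < 360.0):
            raise ValueError("theta_deg must lie in [0, 360)")

    @property
    def theta_rad(self) -> float:
        return float(np.deg2rad(self.theta_deg))


@dataclass
class Scaler:
    """Per-feature mean and standard deviation for standardization."""

    mean: np.ndarray
    sd: np.ndarray


def rotation_angle(endpoint) -> RotationAngle:
    """Angle of ``endpoint`` relative to the origin, in [0, 360) degrees.

    atan2(y, x) converted to degrees, with 360 added when negative.
    """
    x, y = float(endpoint[0]), float(endpoint[1])
    if x == 0.0 and y == 0.0:
        raise ValueError("degenerate trajectory: endpoint coincides with the origin")
    theta = np.degrees(np.arctan2(y, x))
    if theta < 0.0:
        theta += 360.0
    return RotationAngle(theta_deg=theta % 360.0)


def rotate_trajectory(traj: Trajectory) -> Trajectory:
    """Rotate a whole trajectory clockwise so its endpoint lands on the +x axis.

    A trajectory already ending on the positive x-axis (angle 0) is returned
    unchanged, point array and all.
    """
    angle = rotation_angle(traj.endpoint)
    if angle.theta_deg == 0.0:
        return traj
    t = angle.theta_rad
    # clockwise rotation by theta = rotation matrix for -theta
    rot = np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])
    return replace(traj, points=traj.points @ rot.T)


def filter_by_length(
    dataset: TrajectoryDataset, min_len: int = MIN_LEN, max_len: int = MAX_LEN
) -> TrajectoryDataset:
    """Keep trajectories with min_len <= number of points <= max_len."""
    kept = [t for t in dataset if min_len <= len(t) <= max_len]
    return TrajectoryDataset(
        trajectories=kept,
        provenance=dataset.provenance,
        config_snapshot=dataset.config_snapshot,
    )


def rotate_dataset(dataset: TrajectoryDataset) -> TrajectoryDataset:
    return TrajectoryDataset(
        trajectories=[rotate_trajectory(t) for t in dataset],
        provenance=dataset.provenance,
        config_snapshot=dataset.config_snapshot,
    )


def fit_scaler(sequences) -> Scaler:
    """Fit per-feature mean/sd over the unpadded timesteps of ``sequences``.

    ``sequences`` is an iterable of (T_i, F) arrays — only genuine samples,
    never padding rows. A feature with zero variance is rejected.
    """
    stacked = np.concatenate([np.asarray(s, dtype=float) for s in sequences], axis=0)
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        raise ValueError(f"zero-variance feature(s) at index {zero.tolist()}")
    return Scaler(mean=mean, sd=sd)


def apply_scaler(scaler: Scaler, values: np.ndarray) -> np.ndarray:
    return (np.asarray(values, dtype=float) - scaler.mean) / scaler.sd


def pad_sequence(
    values: np.ndarray, target_len: int = TARGET_LEN, pad_value: float = PAD_VALUE
) -> np.ndarray:
    """Append ``pad_value`` rows so the sequence has exactly ``target_len`` rows."""
    values = np.asarray(values, dtype=float)
    t0 = values.shape[0]
    if t0 > target_len:
        raise ValueError(f"sequence of length {t0} exceeds target length {target_len}")
    if t0 == target_len:
        return values.copy()
    pad = np.full((target_len - t0, values.shape[1]), pad_value)
    return np.vstack([values, pad])


def encode_label(group: str) -> tuple:
    """TD -> (1, 0); ASD -> (0, 1)."""
    try:
        return _LABELS[group]
    except KeyError:
        raise ValueError(
            f"unknown group label {group!r}; allowed labels are {set(_LABELS)}"
        ) from None


def decode_label(pair) -> str:
    pair = tuple(float(v) for v in pair)
    for group, onehot in _LABELS.items():
        if pair == onehot:
            return group
    raise ValueError(f"not a valid one-hot label: {pair!r}")
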