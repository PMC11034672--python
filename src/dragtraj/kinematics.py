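"""Point-to-point kinematics and model-input feature tensors.

"Velocity" here is the nonnegative speed: the Euclidean distance between
consecutive samples divided by the sampling interval. Acceleration is the
first difference of that speed series, again divided by dt, and can be
negative. Both series are aligned with the trajectory points, with the
first entry zero-filled (no preceding point to difference against).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trajectory, TrajectoryDataset
from . import preprocess

FEATURE_MODES = ("two_feature", "four_feature")


@dataclass
class KinematicSeries:
    speeds: np.ndarray  # screen-units / s, speeds[0] = 0
    accelerations: np.ndarray  # screen-units / s^2, accelerations[0] = 0
    dt: float


@dataclass
class FeatureTensor:
    """Standardized, zero-padded model input.

    ``sequences`` is (N, target_len, F) with F = 2 (x, y) or F = 4
    (x, y, speed, acceleration); ``labels`` is (N, 2) one-hot with TD =
    (1, 0) and ASD = (0, 1); ``true_lengths`` gives the unpadded length of
    each sequence.
    """

    sequences: np.ndarray
    labels: np.ndarray
    ids: list
    subject_ids: list
    true_lengths: np.ndarray
    feature_mode: str

    @property
    def n_features(self) -> int:
        return self.sequences.shape[2]


def step_speeds(traj: Trajectory) -> np.ndarray:
    """Per-sample speed; entry 0 is zero-filled."""
    if traj.dt <= 0:
        raise ValueError("dt must be positive")
    steps = np.linalg.norm(np.diff(traj.points, axis=0), axis=1)
    return np.concatenate([[0.0], steps / traj.dt])


def step_accelerations(speeds: np.ndarray, dt: float) -> np.ndarray:
    """Per-sample acceleration from a speed series; entry 0 is zero-filled."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    speeds = np.asarray(speeds, dtype=float)
    return np.concatenate([[0.0], np.diff(speeds) / dt])


def kinematic_series(traj: Trajectory) -> KinematicSeries:
    speeds = step_speeds(traj)
    return KinematicSeries(
        speeds=speeds,
        accelerations=step_accelerations(speeds, traj.dt),
        dt=traj.dt,
    )


def mean_acceleration(traj: Trajectory) -> float:
    """Signed per-trajectory mean acceleration (zero-filled entry included)."""
    return float(np.mean(kinematic_series(traj).accelerations))


def mean_abs_acceleration(traj: Trajectory) -> float:
    """Mean |acceleration|; the generator's controlled group contrast."""
    return float(np.mean(np.abs(kinematic_series(traj).accelerations)))


def raw_features(traj: Trajectory, mode: str) -> np.ndarray:
    """Unstandardized (T, F) feature grid for one trajectory."""
    if mode == "two_feature":
        return np.array(traj.points, dtype=float)
    if mode == "four_feature":
        ks = kinematic_series(traj)
        return np.column_stack([traj.points, ks.speeds, ks.accelerations])
    raise ValueError(f"unknown feature mode {mode!r}; choose from {FEATURE_MODES}")


def build_feature_tensor(
    dataset: TrajectoryDataset,
    mode: str,
    scaler: "preprocess.Scaler | None" = None,
    scaler_scope: str = "train_only",
    train_ids: "set | None" = None,
    target_len: int = 69,
) -> tuple:
    """Assemble the (N, target_len, F) model tensor for ``dataset``.

    The dataset is expected to be already rotated and length-filtered.
    Standardization statistics are fit on the unpadded timesteps of the
    trajectories listed in ``train_ids`` (``scaler_scope='train_only'``) or
    of the whole dataset (``'global'``), unless a pre-fit ``scaler`` is
    supplied. Returns ``(FeatureTensor, Scaler)``.
    """
    if mode not in FEATURE_MODES:
        raise ValueError(f"unknown feature mode {mode!r}; choose from {FEATURE_MODES}")
    raw = [raw_features(t, mode) for t in dataset]
    ids = [t.trajectory_id for t in dataset]

    if scaler is None:
        if scaler_scope == "train_only":
            if train_ids is None:
                raise ValueError("train_ids required for scaler_scope='train_only'")
            fit_values = [r for r, i in zip(raw, ids) if i in train_ids]
            if not fit_values:
                raise ValueError("train_ids matched no trajectories")
        elif scaler_scope == "global":
            fit_values = raw
        else:
            raise ValueError(f"unknown scaler_scope {scaler_scope!r}")
        scaler = preprocess.fit_scaler(fit_values)

    sequences = np.zeros((len(raw), target_len, raw[0].shape[1] if raw else 0))
    true_lengths = np.zeros(len(raw), dtype=int)
    labels = np.zeros((len(raw), 2))
    for k, (r, traj) in enumerate(zip(raw, dataset)):
        standardized = preprocess.apply_scaler(scaler, r)
        sequences[k] = preprocess.pad_sequence(standardized, target_len=target_len)
        true_lengths[k] = len(r)
        labels[k] = preprocess.encode_label(traj.group)

    tensor = FeatureTensor(
        sequences=sequences,
        labels=labels,
        ids=ids,
        subject_ids=[t.subject_id for t in dataset],
        true_lengths=true_lengths,
        feature_mode=mode,
    )
    return tensor, scaler
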