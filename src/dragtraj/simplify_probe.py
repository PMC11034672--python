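"""Equidistant trajectory simplification and the acceleration probe.

Simplifying a trajectory keeps M = round(N * p) of its N points at
equidistant indices (both endpoints always retained) while the nominal
sampling interval is unchanged — so a simplified trajectory covers the
same path with fewer, larger steps, which raises its apparent speeds and
accelerations. Simplified trajectories with fewer than 20 points are
excluded, mirroring the minimum retained length of the classification
pipeline.

The correlation probe quantifies how much a trained classifier's ASD
probability tracks a trajectory's (raw, signed) mean acceleration: it
scores original plus simplified trajectories and reports the Pearson
correlation between the two quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats

from .core import Trajectory, TrajectoryDataset
from . import kinematics, model as model_mod, preprocess

RETENTION_PERCENTAGES = (0.35, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90)
MIN_POINTS = 20

__all__ = [
    "RETENTION_PERCENTAGES",
    "SimplifiedTrajectory",
    "simplify",
    "generate_simplified_set",
    "pearson",
    "correlation_probe",
    "CorrelationResult",
]


@dataclass
class SimplifiedTrajectory:
    parent_id: str
    retention_p: float
    kept_indices: np.ndarray
    trajectory: Trajectory


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    model_tag: str


def _round_half_up(x) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def simplify(
    traj: Trajectory, p: float, min_points: int = MIN_POINTS
) -> SimplifiedTrajectory | None:
    """Keep a fraction ``p`` of the trajectory's points at equidistant indices.

    M = round(N*p) (half-up). Kept index i (for i = 0..M-1) is
    round(i * (N-1) / (M-1)), so the first and last points are always
    retained and the kept indices are strictly increasing. Returns ``None``
    (excluded) when M < ``min_points``.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"retention fraction must lie in (0, 1], got {p}")
    n = len(traj)
    m = int(_round_half_up(n * p))
    if m < min_points:
        return None
    if m >= n:
        indices = np.arange(n)
    else:
        indices = _round_half_up(np.arange(m) * (n - 1) / (m - 1))
    child = Trajectory(
        trajectory_id=f"{traj.trajectory_id}_p{int(round(p * 100))}",
        subject_id=traj.subject_id,
        group=traj.group,
        points=traj.points[indices],
        dt=traj.dt,
        target=traj.target,
    )
    return SimplifiedTrajectory(
        parent_id=traj.trajectory_id,
        retention_p=p,
        kept_indices=indices,
        trajectory=child,
    )


def generate_simplified_set(
    dataset: TrajectoryDataset,
    percentages=RETENTION_PERCENTAGES,
    include_originals: bool = True,
    min_points: int = MIN_POINTS,
) -> TrajectoryDataset:
    """All non-excluded simplifications of every trajectory in ``dataset``.

    Deterministic: the simplification rule has no randomness. Children carry
    their parent's group label and subject id.
    """
    out = list(dataset.trajectories) if include_originals else []
    for traj in dataset:
        for p in percentages:
            simplified = simplify(traj, p, min_points=min_points)
            if simplified is not None:
                out.append(simplified.trajectory)
    return TrajectoryDataset(
        trajectories=out,
        provenance=dataset.provenance,
        config_snapshot=dataset.config_snapshot,
    )


def pearson(x, y) -> tuple:
    """Pearson r and the two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 samples, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    result = _scipy_stats.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)


def correlation_probe(
    model: "model_mod.ClassifierModel",
    dataset: TrajectoryDataset,
    scaler: "preprocess.Scaler",
    accel_range: tuple | None = None,
    target_len: int = 69,
) -> CorrelationResult:
    """Pearson correlation between mean acceleration and predicted p_ASD.

    Mean acceleration is computed on the raw (pre-standardization)
    trajectory; predictions use features standardized with the model's
    training ``scaler``. ``accel_range = (lo, hi)`` optionally restricts the
    probe to trajectories whose mean acceleration falls in that interval.
    """
    accels = np.array([kinematics.mean_acceleration(t) for t in dataset])
    if accel_range is not None:
        lo, hi = accel_range
        keep = (accels >= lo) & (accels <= hi)
    else:
        keep = np.ones(len(accels), dtype=bool)
    kept_trajs = [t for t, k in zip(dataset, keep) if k]
    if len(kept_trajs) < 3:
        raise ValueError(
            f"fewer than 3 trajectories retained by accel_range {accel_range}"
        )

    sequences = np.zeros((len(kept_trajs), target_len, model.n_features))
    for i, traj in enumerate(kept_trajs):
        raw = kinematics.raw_features(traj, model.feature_mode)
        sequences[i] = preprocess.pad_sequence(
            preprocess.apply_scaler(scaler, raw), target_len=target_len
        )
    p_asd = model_mod.predict_proba(model, sequences)[:, 1]

    r, p_value = pearson(accels[keep], p_asd)
    return CorrelationResult(
        r=r, p_value=p_value, n=len(kept_trajs), model_tag=model.feature_mode
    )


def probe_pairs(
    model: "model_mod.ClassifierModel",
    dataset: TrajectoryDataset,
    scaler: "preprocess.Scaler",
    target_len: int = 69,
) -> list:
    """(trajectory_id, mean_acceleration, p_ASD) rows for external plotting."""
    rows = []
    for traj in dataset:
        raw = kinematics.raw_features(traj, model.feature_mode)
        seq = preprocess.pad_sequence(
            preprocess.apply_scaler(scaler, raw), target_len=target_len
        )
        p = model_mod.predict_proba(model, seq[None])[0, 1]
        rows.append((traj.trajectory_id, kinematics.mean_acceleration(traj), float(p)))
    return rows
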