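"""Shared domain types for touchscreen drag-trajectory analysis.

A *trajectory* is the ordered sequence of (x, y) finger positions recorded
while a subject drags an image from the screen centre to one of eight fixed
targets, sampled at a fixed rate (nominally 20 Hz, i.e. dt = 0.05 s).
Each trajectory carries a subject identifier and a group label, either
``"TD"`` (typically developing) or ``"ASD"`` (autism spectrum disorder).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

GROUPS = ("TD", "ASD")

#: Nominal sampling interval in seconds (20 Hz acquisition).
DEFAULT_DT = 0.05


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic trajectory generator.

    The defaults mirror the acquisition regime the analysis assumes: 20 Hz
    sampling and retained trajectory lengths between 20 and 69 points, with
    a dataset scale of 20 subjects split evenly between the two groups.

    ``accel_effect`` is the standardized between-group difference (Cohen's d)
    in per-trajectory mean |acceleration| that the generator realizes; 0
    yields statistically indistinguishable groups.
    """

    n_subjects_per_group: int = 10
    trajectories_per_subject: int = 37
    sampling_rate: float = 20.0
    min_len: int = 20
    max_len: int = 69
    accel_effect: float = 2.0
    jitter_sd: float = 0.6
    submovement_rate_by_group: dict = field(
        default_factory=lambda: {"TD": 2.0, "ASD": 2.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be >= 1")
        if self.min_len < 2:
            raise ValueError("min_len must be >= 2")
        if self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(**d)


@dataclass
class Trajectory:
    """One drag movement: ordered (x, y) samples plus metadata.

    ``points`` is an (N, 2) float array; the first point is the drag origin
    and the last point is the trajectory endpoint. ``dt`` is the seconds per
    sample. ``target`` is the nominal target-image centre the drag aimed at
    (may differ from the last point by positional noise).
    """

    trajectory_id: str
    subject_id: str
    group: str
    points: np.ndarray
    dt: float = DEFAULT_DT
    target: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if len(self.points) < 2:
            raise ValueError("a trajectory needs at least 2 points")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.group not in GROUPS:
            raise ValueError(
                f"unknown group label {self.group!r}; allowed labels are {set(GROUPS)}"
            )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def endpoint(self) -> np.ndarray:
        return self.points[-1]


@dataclass
class TrajectoryDataset:
    """A collection of trajectories with provenance metadata."""

    trajectories: list
    provenance: str = "synthetic"
    config_snapshot: Optional[GeneratorConfig] = None

    def __post_init__(self) -> None:
        ids = [t.trajectory_id for t in self.trajectories]
        if len(ids) != len(set(ids)):
            raise ValueError("trajectory_ids must be unique")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def group_counts(self) -> dict:
        counts = {g: 0 for g in GROUPS}
        for t in self.trajectories:
            counts[t.group] += 1
        return counts

    def subject_ids(self) -> list:
        seen: dict = {}
        for t in self.trajectories:
            seen.setdefault(t.subject_id, None)
        return list(seen)


@dataclass
class EvalReport:
    """Aggregate evaluation results for one feature mode.

    ``fold_accuracies`` holds the final validation accuracy of each
    cross-validation fold; ``loss_history`` the per-epoch training loss
    averaged across folds. ROC/AUC and sensitivity/specificity are computed
    on the held-out evaluation set from the fold-ensemble's mean predicted
    ASD probability.
    """

    model_tag: str
    fold_accuracies: list
    loss_history: list
    roc_points: list
    auc: float
    sensitivity: float
    specificity: float
    n_validation: int
    config_snapshot: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_tag not in ("two_feature", "four_feature"):
            raise ValueError("model_tag must be 'two_feature' or 'four_feature'")
        for name in ("auc", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for a in self.fold_accuracies:
            if not (0.0 <= a <= 1.0):
                raise ValueError("fold accuracies must lie in [0, 1]")
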