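"""Evaluation protocol: stratified holdout + four-fold cross-validation.

A 15% group-stratified holdout is carved out first and never used for
training; the remaining trajectories are partitioned into k (default 4)
near-equal stratified folds. For each fold a fresh classifier is trained
on the other folds (with standardization fit on that training portion
only) and its final validation accuracy recorded. The holdout is then
scored with the mean predicted ASD probability of the k fold models, from
which the ROC curve, AUC, and sensitivity/specificity at threshold 0.5
are computed. ASD is the positive class throughout.

The default ``trajectory_wise`` splitting assigns individual trajectories
to folds; ``subject_wise`` keeps each subject's trajectories together
(trajectory-wise splitting of a small cohort leaks subject identity
between training and validation — a documented caveat of the protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn import metrics as _skmetrics

from .core import EvalReport, TrajectoryDataset
from . import kinematics, model as model_mod

__all__ = [
    "SplitPlan",
    "make_split",
    "run_experiment",
    "roc_curve",
    "auc",
    "sensitivity_specificity",
    "shuffle_labels",
]


@dataclass
class SplitPlan:
    fold_assignments: dict  # trajectory_id -> fold index
    holdout_ids: set
    strategy: str
    seed: int
    k: int

    def fold_ids(self, fold: int) -> list:
        return [tid for tid, f in self.fold_assignments.items() if f == fold]


def _stratified_holdout_counts(group_sizes: dict, total_holdout: int) -> dict:
    """Per-group holdout counts proportional to group size, summing exactly."""
    n = sum(group_sizes.values())
    shares = {g: total_holdout * size / n for g, size in group_sizes.items()}
    counts = {g: int(np.floor(s)) for g, s in shares.items()}
    remainder = total_holdout - sum(counts.values())
    by_frac = sorted(shares, key=lambda g: shares[g] - counts[g], reverse=True)
    for g in by_frac[:remainder]:
        counts[g] += 1
    return counts


def make_split(
    dataset: TrajectoryDataset,
    k: int = 4,
    holdout_fraction: float = 0.15,
    strategy: str = "trajectory_wise",
    seed: int = 0,
) -> SplitPlan:
    """Build the holdout + k-fold assignment for ``dataset``.

    The holdout has exactly ``floor(holdout_fraction * N)`` trajectories,
    stratified by group. Remaining trajectories are dealt into k folds whose
    sizes differ by at most one (trajectory_wise) or whose subjects are
    balanced (subject_wise).
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)

    if strategy == "trajectory_wise":
        by_group: dict = {}
        for t in dataset:
            by_group.setdefault(t.group, []).append(t.trajectory_id)
        for ids in by_group.values():
            rng.shuffle(ids)
        n = len(dataset)
        holdout_total = int(np.floor(holdout_fraction * n))
        counts = _stratified_holdout_counts(
            {g: len(ids) for g, ids in by_group.items()}, holdout_total
        )
        holdout = set()
        remaining = []
        for g in sorted(by_group):
            holdout.update(by_group[g][: counts[g]])
            remaining.extend(by_group[g][counts[g]:])
        if len(remaining) < k:
            raise ValueError(f"k={k} exceeds the {len(remaining)} non-holdout trajectories")
        # continuous round-robin deal over group-sorted ids keeps both the
        # total fold sizes (<=1 apart) and the per-group stratification
        assignments = {tid: i % k for i, tid in enumerate(remaining)}
        return SplitPlan(assignments, holdout, strategy, seed, k)

    if strategy == "subject_wise":
        by_subject: dict = {}
        subject_group: dict = {}
        for t in dataset:
            by_subject.setdefault(t.subject_id, []).append(t.trajectory_id)
            subject_group[t.subject_id] = t.group
        groups: dict = {}
        for s, g in subject_group.items():
            groups.setdefault(g, []).append(s)
        for subs in groups.values():
            rng.shuffle(subs)
        n = len(dataset)
        target_holdout = holdout_fraction * n
        holdout = set()
        fold_subjects: list = []
        taken = 0.0
        for g in sorted(groups):
            share = target_holdout * sum(len(by_subject[s]) for s in groups[g]) / n
            got = 0
            for s in groups[g]:
                if got < share:
                    holdout.update(by_subject[s])
                    got += len(by_subject[s])
                else:
                    fold_subjects.append(s)
            taken += got
        if len(fold_subjects) < k:
            raise ValueError(f"k={k} exceeds the {len(fold_subjects)} non-holdout subjects")
        assignments = {}
        for i, s in enumerate(fold_subjects):
            for tid in by_subject[s]:
                assignments[tid] = i % k
        return SplitPlan(assignments, holdout, strategy, seed, k)

    raise ValueError(f"unknown split strategy {strategy!r}")


# ------------------------------------------------------------------- metrics

def roc_curve(labels, scores) -> list:
    """ROC points (fpr, tpr) for a threshold sweep over ASD scores.

    ``labels`` may be binary (1 = ASD) or group-label strings. Points run
    from (0, 0) to (1, 1); tied scores collapse to one point.
    """
    y = _as_binary(labels)
    if len(set(y)) < 2:
        raise ValueError("ROC requires both a positive and a negative class")
    fpr, tpr, _ = _skmetrics.roc_curve(y, scores)
    return list(zip(fpr.tolist(), tpr.tolist()))


def auc(roc_points) -> float:
    """Trapezoidal area under a (fpr, tpr) ROC polyline."""
    pts = np.asarray(roc_points, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return np.asarray([1 if v == "ASD" else 0 for v in arr])
    return arr.astype(int)


def sensitivity_specificity(labels, predicted_labels, positive: str = "ASD") -> tuple:
    """(TP/(TP+FN), TN/(TN+FP)) with ASD as the positive class."""
    y = _as_binary(labels)
    pred = _as_binary(predicted_labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present in the true labels")
    tp = int(np.sum((y == 1) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    return tp / (tp + fn), tn / (tn + fp)


def shuffle_labels(dataset: TrajectoryDataset, seed: int = 0) -> TrajectoryDataset:
    """Randomly permute the group labels across trajectories (null model)."""
    rng = np.random.default_rng(seed)
    labels = [t.group for t in dataset]
    perm = rng.permutation(len(labels))
    shuffled = [
        replace(t, group=labels[perm[i]]) for i, t in enumerate(dataset)
    ]
    return TrajectoryDataset(
        trajectories=shuffled,
        provenance=dataset.provenance,
        config_snapshot=dataset.config_snapshot,
    )


# ---------------------------------------------------------------- experiment

def run_experiment(
    dataset: TrajectoryDataset,
    model_cfg: "model_mod.ModelConfig",
    feature_mode: str,
    split_plan: SplitPlan,
    scaler_scope: str = "train_only",
    target_len: int = 69,
    return_artifacts: bool = False,
):
    """Cross-validated training plus holdout ROC evaluation for one mode.

    ``dataset`` must already be rotated and length-filtered. Returns the
    :class:`EvalReport`, or ``(report, artifacts)`` when
    ``return_artifacts`` — artifacts carrying the fold models, scalers, and
    holdout predictions for downstream probing.
    """
    ids = [t.trajectory_id for t in dataset]
    id_to_idx = {tid: i for i, tid in enumerate(ids)}
    holdout_idx = np.array([id_to_idx[t] for t in sorted(split_plan.holdout_ids)])
    if holdout_idx.size == 0:
        raise ValueError("split plan has an empty holdout")

    k = split_plan.k
    fold_accuracies = []
    loss_histories = []
    holdout_probs = []
    fold_models = []
    fold_scalers = []
    for fold in range(k):
        val_ids = set(split_plan.fold_ids(fold))
        train_ids = {
            tid for tid, f in split_plan.fold_assignments.items() if f != fold
        }
        tensor, scaler = kinematics.build_feature_tensor(
            dataset,
            feature_mode,
            scaler_scope=scaler_scope,
            train_ids=train_ids,
            target_len=target_len,
        )
        tr = np.array(sorted(id_to_idx[t] for t in train_ids))
        va = np.array(sorted(id_to_idx[t] for t in val_ids))

        fold_cfg = replace(model_cfg, seed=model_cfg.seed + fold)
        clf = model_mod.build_model(fold_cfg, feature_mode)
        history = model_mod.train(clf, tensor.sequences[tr], tensor.labels[tr], fold_cfg)
        loss_histories.append(history.loss)

        val_probs = model_mod.predict_proba(clf, tensor.sequences[va])
        val_acc = float(
            np.mean((val_probs[:, 1] >= 0.5) == (tensor.labels[va, 1] == 1))
        )
        fold_accuracies.append(val_acc)
        holdout_probs.append(model_mod.predict_proba(clf, tensor.sequences[holdout_idx]))
        fold_models.append(clf)
        fold_scalers.append(scaler)

    mean_probs = np.mean(holdout_probs, axis=0)
    holdout_truth = [dataset.trajectories[i].group for i in holdout_idx]
    roc = roc_curve(holdout_truth, mean_probs[:, 1])
    predicted = ["ASD" if p >= 0.5 else "TD" for p in mean_probs[:, 1]]
    sens, spec = sensitivity_specificity(holdout_truth, predicted)

    report = EvalReport(
        model_tag=feature_mode,
        fold_accuracies=fold_accuracies,
        loss_history=np.mean(loss_histories, axis=0).tolist(),
        roc_points=roc,
        auc=auc(roc),
        sensitivity=sens,
        specificity=spec,
        n_validation=int(holdout_idx.size),
        config_snapshot={
            "model": {
                "lstm_units": model_cfg.lstm_units,
                "learning_rate": model_cfg.learning_rate,
                "epochs": model_cfg.epochs,
                "batch_size": model_cfg.batch_size,
                "seed": model_cfg.seed,
            },
            "split": {"k": k, "strategy": split_plan.strategy, "seed": split_plan.seed},
            "scaler_scope": scaler_scope,
        },
    )
    if return_artifacts:
        artifacts = {
            "models": fold_models,
            "scalers": fold_scalers,
            "holdout_ids": sorted(split_plan.holdout_ids),
            "holdout_probs": mean_probs,
        }
        return report, artifacts
    return report
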