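"""File formats: long-format trajectory CSV and JSON evaluation reports.

Trajectory CSV schema (UTF-8, '.' decimal, header required)::

    trajectory_id,subject_id,group,t_index,x,y

with one row per sampled point, ordered by trajectory_id then t_index.
A companion JSON sidecar ``<name>.meta.json`` records the generator config
snapshot and the sampling interval; without it, dt defaults to 0.05 s
(20 Hz).

Evaluation reports are schema-versioned JSON documents holding per-fold
accuracies, the averaged loss history, ROC points, AUC, and
sensitivity/specificity.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DEFAULT_DT, EvalReport, GeneratorConfig, Trajectory, TrajectoryDataset

REPORT_SCHEMA_VERSION = 1

_CSV_COLUMNS = ["trajectory_id", "subject_id", "group", "t_index", "x", "y"]
_ALLOWED_GROUPS = {"TD", "ASD"}


class SchemaError(ValueError):
    """The file does not match the expected column schema."""


class DataError(ValueError):
    """The file parses but violates a data contract."""


def _sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.json") if p.suffix != ".csv" \
        else p.with_name(p.stem + ".meta.json")


def write_trajectories(dataset: TrajectoryDataset, path) -> None:
    """Write the dataset as long-format CSV plus a JSON metadata sidecar."""
    rows = []
    for traj in dataset:
        for t_index, (x, y) in enumerate(traj.points):
            rows.append((traj.trajectory_id, traj.subject_id, traj.group, t_index, x, y))
    frame = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    frame = frame.sort_values(["trajectory_id", "t_index"], kind="stable")
    frame.to_csv(path, index=False)

    meta = {
        "provenance": dataset.provenance,
        "dt": dataset.trajectories[0].dt if len(dataset) else DEFAULT_DT,
        "targets": {
            t.trajectory_id: list(t.target) for t in dataset if t.target is not None
        },
        "config_snapshot": (
            dataset.config_snapshot.to_dict() if dataset.config_snapshot else None
        ),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_trajectories(path, format: str = "csv") -> TrajectoryDataset:
    """Read a long-format trajectory CSV (and its sidecar, if present)."""
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}")
    frame = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    bad_groups = set(frame["group"].unique()) - _ALLOWED_GROUPS
    if bad_groups:
        raise DataError(
            f"unknown group label(s) {sorted(bad_groups)}; "
            f"allowed labels are {_ALLOWED_GROUPS}"
        )

    dt = DEFAULT_DT
    targets: dict = {}
    config = None
    provenance = "file"
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        dt = meta.get("dt", DEFAULT_DT)
        targets = meta.get("targets", {})
        provenance = meta.get("provenance", "file")
        if meta.get("config_snapshot"):
            config = GeneratorConfig.from_dict(meta["config_snapshot"])

    trajectories = []
    for tid, g in frame.groupby("trajectory_id", sort=True):
        t_index = g["t_index"].to_numpy()
        order = np.argsort(t_index, kind="stable")
        if np.any(np.diff(t_index[order]) <= 0):
            raise DataError(f"non-monotone t_index within trajectory {tid!r}")
        g = g.iloc[order]
        trajectories.append(
            Trajectory(
                trajectory_id=str(tid),
                subject_id=str(g["subject_id"].iloc[0]),
                group=str(g["group"].iloc[0]),
                points=g[["x", "y"]].to_numpy(dtype=float),
                dt=dt,
                target=tuple(targets[str(tid)]) if str(tid) in targets else None,
            )
        )
    return TrajectoryDataset(
        trajectories=trajectories, provenance=provenance, config_snapshot=config
    )


# ------------------------------------------------------------------- reports

_REQUIRED_REPORT_KEYS = [
    "model_tag",
    "fold_accuracies",
    "loss_history",
    "roc_points",
    "auc",
    "sensitivity",
    "specificity",
    "n_validation",
]


def write_report(report: EvalReport, path) -> None:
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "model_tag": report.model_tag,
        "fold_accuracies": list(map(float, report.fold_accuracies)),
        "loss_history": list(map(float, report.loss_history)),
        "roc_points": [[float(a), float(b)] for a, b in report.roc_points],
        "auc": float(report.auc),
        "sensitivity": float(report.sensitivity),
        "specificity": float(report.specificity),
        "n_validation": int(report.n_validation),
        "config_snapshot": report.config_snapshot,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_report(path) -> EvalReport:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise DataError(f"malformed report JSON: {exc}") from exc
    missing = [k for k in _REQUIRED_REPORT_KEYS if k not in doc]
    if missing:
        raise DataError(f"report missing required key(s): {missing}")
    return EvalReport(
        model_tag=doc["model_tag"],
        fold_accuracies=doc["fold_accuracies"],
        loss_history=doc["loss_history"],
        roc_points=[tuple(p) for p in doc["roc_points"]],
        auc=doc["auc"],
        sensitivity=doc["sensitivity"],
        specificity=doc["specificity"],
        n_validation=doc["n_validation"],
        config_snapshot=doc.get("config_snapshot", {}),
    )
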