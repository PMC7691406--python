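"""Tabular I/O and run manifests.

All artifacts are plain text: TSV for matrices and per-point tables,
JSON for reports and ladders, YAML for configuration.  Floating-point
values round-trip at full precision (shortest-repr serialization);
undefined reachability/core distances serialize as the string ``inf``.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .containers import ClusteringResult, DensityParams, FeatureMatrix, GroupLabels
from .dbscan import EpsilonPlot
from .optics import ReachabilityProfile
from .robustness import RCLANResult

_LABEL_COLS = ["group", "age", "gender", "motion"]


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    fm.to_frame().rename_axis("subject").to_csv(path, sep="\t")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate subject ID {dup!r} in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    return FeatureMatrix(
        values=values,
        feature_ids=[str(c) for c in df.columns],
        subject_ids=[str(i) for i in df.index],
    )


def write_labels(labels: GroupLabels, path: str | Path) -> None:
    df = labels.covariates.copy()
    df.insert(0, "group", labels.labels)
    df.rename_axis("subject").to_csv(path, sep="\t")


def read_labels(path: str | Path) -> GroupLabels:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    missing = [c for c in _LABEL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"labels file {path} missing columns {missing}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate subject ID {dup!r} in {path}")
    df.index = df.index.astype(str)
    return GroupLabels(
        labels=[str(g) for g in df["group"]],
        covariates=df[["age", "gender", "motion"]].astype(float),
    )


def check_alignment(fm: FeatureMatrix, labels: GroupLabels) -> None:
    """Referential integrity between a feature matrix and a labels table."""
    missing = [s for s in fm.subject_ids if s not in set(labels.subject_ids)]
    if missing:
        raise ValueError(f"labels missing subject(s): {missing[:5]}")
    if fm.subject_ids != labels.subject_ids:
        raise ValueError("subject order differs between features and labels")


def write_timeseries_csv(data: np.ndarray, roi_ids: list[str], path: str | Path) -> None:
    """One subject's series as timepoints x ROIs CSV (header = ROI IDs)."""
    pd.DataFrame(data.T, columns=roi_ids).to_csv(path, index=False)


def read_timeseries_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, float_precision="round_trip")
    return df.to_numpy(dtype=float).T, [str(c) for c in df.columns]


def write_assignments(
    result: ClusteringResult, subject_ids: list[str], path: str | Path
) -> None:
    pd.DataFrame(
        {"subject": subject_ids, "cluster": result.assignment}
    ).to_csv(path, sep="\t", index=False)


def write_epsilon_plot(plot: EpsilonPlot, path: str | Path) -> None:
    pd.DataFrame(
        {"eps": plot.eps_grid, "n_clusters": plot.n_clusters_at}
    ).to_csv(path, sep="\t", index=False)


def write_reachability(
    profile: ReachabilityProfile, subject_ids: list[str], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "order_position": np.arange(profile.n_points),
            "point_id": [subject_ids[i] for i in profile.ordering],
            "reach": profile.reach,
            "core_dist": profile.core_dist,
        }
    ).to_csv(path, sep="\t", index=False)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return "inf" if np.isinf(f) else ("nan" if np.isnan(f) else f)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def write_json(obj: Any, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, repr floats."""
    Path(path).write_text(
        json.dumps(_jsonable(obj), sort_keys=True, indent=2, separators=(",", ": "))
        + "\n"
    )


def write_rclan(result: RCLANResult, path: str | Path) -> None:
    write_json(result, path)


def read_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def run_manifest(stage: str, params: dict, shapes: dict, path: str | Path) -> None:
    """Append a stage record (parameters, seeds, data shapes) to a JSON
    manifest so every reported number is traceable."""
    p = Path(path)
    records = json.loads(p.read_text()) if p.exists() else []
    records.append({"stage": stage, "params": _jsonable(params), "shapes": _jsonable(shapes)})
    p.write_text(json.dumps(records, sort_keys=True, indent=2) + "\n")
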