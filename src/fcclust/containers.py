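"""Shared data containers for the connectivity-clustering pipeline.

The pipeline moves data through three shapes: per-subject ROI time series,
a subjects x features matrix (the clustering substrate), and per-subject
cluster assignments.  All containers are thin dataclasses around numpy
arrays with validation at construction time.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_NAMES = ("control", "EMCI", "LMCI", "AD")

#: label used for points that belong to no cluster
NOISE_LABEL = 0


class ConfigError(ValueError):
    """Raised when a configuration object violates its invariants."""


@dataclass
class ROITimeSeriesSet:
    """Per-subject ROI time series: ``data[subject, roi, timepoint]``."""

    data: np.ndarray
    subject_ids: list[str]
    roi_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("time-series data must be 3-d (subjects x ROIs x timepoints)")
        n_subj, n_roi, n_t = self.data.shape
        if n_t < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time-series data contains non-finite values")
        if len(self.subject_ids) != n_subj:
            raise ValueError("subject_ids length does not match data")
        if len(self.roi_ids) != n_roi:
            raise ValueError("roi_ids length does not match data")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]


@dataclass
class FeatureMatrix:
    """Subjects x features matrix with feature and subject identifiers.

    Feature identifiers are strings.  Features derived from ROI pairs use
    the convention ``"<roi_a>~<roi_b>|<measure>"`` with ``measure`` one of
    ``SFC`` (static correlation) or ``DFCvar`` (variance of sliding-window
    correlation); synthetic feature cohorts use opaque ``"f<k>"`` labels.
    """

    values: np.ndarray
    feature_ids: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-d (subjects x features)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains missing or non-finite values")
        if len(self.feature_ids) != self.values.shape[1]:
            raise ValueError("feature_ids length does not match column count")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length does not match row count")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature identifiers")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject identifiers")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_columns(self, idx: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(idx, dtype=int)
        return FeatureMatrix(
            values=self.values[:, idx].copy(),
            feature_ids=[self.feature_ids[i] for i in idx],
            subject_ids=list(self.subject_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.feature_ids)


@dataclass
class GroupLabels:
    """Per-subject diagnostic group plus nuisance covariates.

    ``covariates`` holds columns ``age`` (years), ``gender`` (0/1 code) and
    ``motion`` (arbitrary units), indexed by subject identifier in the same
    order as ``labels``.
    """

    labels: list[str]
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if len(self.labels) != len(self.covariates):
            raise ValueError("labels and covariates disagree on subject count")
        for col in ("age", "gender", "motion"):
            if col not in self.covariates.columns:
                raise ValueError(f"covariates missing required column {col!r}")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.covariates.index)

    @property
    def n_subjects(self) -> int:
        return len(self.labels)

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def codes(self) -> np.ndarray:
        """Integer group codes in first-appearance order."""
        names = self.group_names
        lut = {g: i for i, g in enumerate(names)}
        return np.array([lut[g] for g in self.labels], dtype=int)


@dataclass(frozen=True)
class DensityParams:
    """DBSCAN/OPTICS density threshold: neighborhood radius and MinPts."""

    eps: float
    min_pts: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.eps) and self.eps > 0):
            raise ConfigError("eps must be finite and positive")
        if self.min_pts < 1:
            raise ConfigError("min_pts must be >= 1")


@dataclass
class ClusteringResult:
    """Per-point cluster assignment; 0 marks outliers, clusters are 1..K."""

    assignment: np.ndarray
    params: DensityParams | None = None
    n_clusters: int = field(init=False)

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.ndim != 1:
            raise ValueError("assignment must be 1-d")
        if np.any(self.assignment < 0):
            raise ValueError("labels must be >= 0 (0 = outlier)")
        positive = np.unique(self.assignment[self.assignment > 0])
        if positive.size and not np.array_equal(positive, np.arange(1, positive.size + 1)):
            raise ValueError("cluster labels must be contiguous 1..K")
        self.n_clusters = int(positive.size)

    @property
    def n_outliers(self) -> int:
        return int(np.sum(self.assignment == NOISE_LABEL))
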