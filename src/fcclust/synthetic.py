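"""Synthetic cohorts with controllable group structure.

Two generators are provided.  ``generate_feature_cohort`` draws a
subjects x features matrix directly: each diagnostic group is a
multivariate Gaussian whose centroid is displaced from the others by a
controllable amount, emulating a covariate-cleaned connectivity-feature
matrix.  ``generate_roi_timeseries`` goes one level deeper and simulates
ROI time series in which designated ROI pairs share a latent signal:

* the pair's instantaneous correlation level sets the *static*
  connectivity (shifted between groups by ``sfc_effect``), and
* a sinusoidal modulation of that correlation sets the *temporal
  variability* of connectivity (amplitude shifted by ``dfc_effect``),

so the two feature families the downstream pipeline contrasts — static
correlation and sliding-window correlation variance — are dialled
independently.  For an affected pair the generated series are
``x_t = z_t`` and ``y_t = rho_t * z_t + sqrt(1 - rho_t^2) * e_t`` with unit
white ``z, e``; the closed-form instantaneous correlation is exactly
``rho_t``, and the full-series static correlation converges to the time
average of ``rho_t`` as the series grows.

Demographic covariates (age, gender, motion) are generated per group from
the cohort demographics but, by default, carry no effect on features; a
confound switch injects an age effect so covariate adjustment can be
tested under both regimes.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    GROUP_NAMES,
    ConfigError,
    FeatureMatrix,
    GroupLabels,
    ROITimeSeriesSet,
)

# Group demographics (age mean/sd in years, male proportion) for
# control / EMCI / LMCI / AD cohorts.
_AGE_MEAN = (74.5, 72.2, 71.4, 73.1)
_AGE_SD = (5.9, 5.9, 8.6, 7.4)
_MALE_PROP = (15 / 36, 18 / 34, 21 / 34, 13 / 29)


@dataclass(frozen=True)
class CovariateModel:
    """Per-group demographic model for nuisance covariates."""

    age_mean: tuple[float, ...] = _AGE_MEAN
    age_sd: tuple[float, ...] = _AGE_SD
    male_prop: tuple[float, ...] = _MALE_PROP
    motion_sd: float = 1.0  # unit-scale head-motion score


@dataclass
class SyntheticCohortConfig:
    """Configuration for synthetic cohorts.

    ``sfc_effect`` is the between-group shift of connectivity strength in
    correlation units: for feature cohorts it is the per-feature RMS
    centroid displacement between groups; for time-series cohorts it is
    the increment of the affected pairs' correlation level between the two
    ends of the diagnostic spectrum.  ``dfc_effect`` is the corresponding
    increment of the sinusoidal correlation-modulation amplitude, which
    drives sliding-window correlation variance.
    """

    group_sizes: list[int] = field(default_factory=lambda: [35, 34, 34, 29])
    group_names: tuple[str, ...] = GROUP_NAMES
    n_rois: int = 200
    n_timepoints: int = 135
    n_features: int = 100
    sfc_effect: float = 0.20
    dfc_effect: float = 0.25
    within_group_sd: float = 0.10
    n_affected_pairs: int = 100
    base_corr: float = 0.20          # affected-pair correlation in the reference group
    base_amplitude: float = 0.05     # modulation amplitude in the reference group
    modulation_period: tuple[float, float] = (40.0, 80.0)  # timepoints
    base_level: float = 0.30         # additive offset of feature-cohort centroids
    # Per-group multipliers of within_group_sd.  "demographic" (default)
    # mirrors the cohort's demographic heterogeneity (age-SD ratios
    # 5.9/5.9/8.6/7.4 across control/EMCI/LMCI/AD, normalized to mean 1):
    # patient groups, especially LMCI, are more dispersed than controls,
    # so cluster densities differ between diagnostic groups as they do in
    # practice.  None means homogeneous; a tuple sets multipliers directly.
    group_dispersion: tuple[float, ...] | str | None = "demographic"
    centroid_mode: str = "simplex"   # "simplex" (equidistant) or "spectrum" (ordered)
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    covariate_confound: float = 0.0  # per-year age slope injected into features
    seed: int = 0

    def validate(self) -> None:
        if not self.group_sizes or any(g <= 0 for g in self.group_sizes):
            raise ConfigError("group_sizes must be positive integers")
        if len(self.group_sizes) != len(self.group_names):
            raise ConfigError("group_sizes and group_names disagree")
        if self.n_rois <= 0 or self.n_features <= 0:
            raise ConfigError("n_rois and n_features must be positive")
        if self.n_timepoints < 2:
            raise ConfigError("n_timepoints must be >= 2")
        if self.sfc_effect < 0 or self.dfc_effect < 0:
            raise ConfigError("effect sizes must be >= 0")
        if self.within_group_sd <= 0:
            raise ConfigError("within_group_sd must be > 0")
        if self.n_affected_pairs <= 0:
            raise ConfigError("n_affected_pairs must be positive")
        if 2 * self.n_affected_pairs > self.n_rois:
            raise ConfigError(
                "n_affected_pairs exceeds the number of disjoint ROI pairs "
                f"({self.n_rois} ROIs support at most {self.n_rois // 2})"
            )
        if self.centroid_mode not in ("simplex", "spectrum"):
            raise ConfigError("centroid_mode must be 'simplex' or 'spectrum'")
        if self.group_dispersion is not None and not isinstance(self.group_dispersion, str):
            if len(self.group_dispersion) != len(self.group_sizes):
                raise ConfigError("group_dispersion length must match group_sizes")
            if any(s <= 0 for s in self.group_dispersion):
                raise ConfigError("group_dispersion multipliers must be positive")
        if isinstance(self.group_dispersion, str) and self.group_dispersion != "demographic":
            raise ConfigError("group_dispersion must be 'demographic', None or a tuple")

    def dispersion_scales(self) -> np.ndarray:
        """Per-group within-dispersion multipliers (mean 1)."""
        n_groups = len(self.group_sizes)
        if self.group_dispersion is None:
            return np.ones(n_groups)
        if self.group_dispersion == "demographic":
            pat = np.array(_AGE_SD[:n_groups] if n_groups <= len(_AGE_SD)
                           else _AGE_SD * (n_groups // len(_AGE_SD) + 1))[:n_groups]
            return pat / pat.mean()
        return np.asarray(self.group_dispersion, dtype=float)

    def dispersion_of(self, g: int) -> float:
        """Within-group standard deviation of group ``g``."""
        return self.within_group_sd * float(self.dispersion_scales()[g])

    @property
    def n_subjects(self) -> int:
        return int(sum(self.group_sizes))

    def replace(self, **kw) -> "SyntheticCohortConfig":
        return dataclasses.replace(self, **kw)


def _group_scores(n_groups: int) -> np.ndarray:
    """Disease-spectrum position of each group on [0, 1]."""
    if n_groups == 1:
        return np.zeros(1)
    return np.arange(n_groups) / (n_groups - 1)


def _make_covariates(config: SyntheticCohortConfig, rng: np.random.Generator) -> GroupLabels:
    cm = config.covariate_model
    n_groups = len(config.group_sizes)
    labels: list[str] = []
    rows = []
    for g, size in enumerate(config.group_sizes):
        age = rng.normal(cm.age_mean[g % len(cm.age_mean)], cm.age_sd[g % len(cm.age_sd)], size)
        gender = (rng.random(size) < cm.male_prop[g % len(cm.male_prop)]).astype(int)
        motion = np.abs(rng.normal(0.0, cm.motion_sd, size))
        labels.extend([config.group_names[g]] * size)
        for a, s, m in zip(age, gender, motion):
            rows.append((a, s, m))
    subj = [f"sub{i:04d}" for i in range(config.n_subjects)]
    cov = pd.DataFrame(rows, columns=["age", "gender", "motion"], index=subj)
    del n_groups
    return GroupLabels(labels=labels, covariates=cov)


def _simplex_directions(n_groups: int, n_features: int) -> np.ndarray:
    """Mutually orthogonal unit vectors spread across all features.

    Uses sign patterns from a tiled order-4 Hadamard matrix, so every
    feature carries part of every group contrast (exactly orthogonal when
    the feature count is a multiple of 4; trailing features are padded
    with the repeating pattern, which preserves near-orthogonality).
    """
    h4 = np.array(
        [[1, 1, 1, 1], [1, -1, 1, -1], [1, 1, -1, -1], [1, -1, -1, 1]], dtype=float
    )
    reps = int(np.ceil(n_features / 4))
    pats = np.tile(h4, (1, reps))[:, :n_features]
    pats = pats[np.arange(n_groups) % 4]
    return pats / np.linalg.norm(pats, axis=1, keepdims=True)


def group_centroids(config: SyntheticCohortConfig) -> np.ndarray:
    """Group centroids in feature space (n_groups x n_features).

    Pairwise centroid distance is ``sfc_effect * sqrt(n_features)`` in
    simplex mode (``sfc_effect`` is the per-feature RMS displacement);
    spectrum mode places groups on a line with that distance between
    adjacent groups, mimicking a disease continuum.
    """
    n_groups = len(config.group_sizes)
    d = config.n_features
    delta = config.sfc_effect * np.sqrt(d)
    dirs = _simplex_directions(max(n_groups, 2), d)
    if config.centroid_mode == "simplex":
        cents = (delta / np.sqrt(2.0)) * dirs[:n_groups]
    else:  # spectrum: ordered along one direction
        pos = np.arange(n_groups, dtype=float)
        cents = np.outer(pos * delta, dirs[0])
    return cents + config.base_level


def generate_feature_cohort(
    config: SyntheticCohortConfig,
) -> tuple[FeatureMatrix, GroupLabels]:
    """Draw a subjects x features cohort with group-dependent centroids.

    Each group's rows are i.i.d. Gaussian around its centroid with
    isotropic standard deviation ``within_group_sd``.  With
    ``covariate_confound > 0`` an age effect of that many units per year
    (relative to the grand age mean) is added to the first quarter of the
    features, for testing covariate adjustment.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = _make_covariates(config, rng)
    cents = group_centroids(config)
    blocks = []
    for g, size in enumerate(config.group_sizes):
        blocks.append(cents[g] + rng.normal(0.0, config.dispersion_of(g), (size, config.n_features)))
    values = np.vstack(blocks)
    if config.covariate_confound > 0:
        age = labels.covariates["age"].to_numpy()
        n_conf = max(1, config.n_features // 4)
        values[:, :n_conf] += config.covariate_confound * (age - age.mean())[:, None]
    fm = FeatureMatrix(
        values=values,
        feature_ids=[f"f{j:04d}" for j in range(config.n_features)],
        subject_ids=labels.subject_ids,
    )
    return fm, labels


def affected_pairs(config: SyntheticCohortConfig) -> list[tuple[int, int]]:
    """ROI index pairs carrying group effects: disjoint pairs (2i, 2i+1)."""
    return [(2 * i, 2 * i + 1) for i in range(config.n_affected_pairs)]


def generate_roi_timeseries(
    config: SyntheticCohortConfig,
) -> tuple[ROITimeSeriesSet, GroupLabels]:
    """Simulate per-subject ROI time series with latent-pair structure.

    For subject in group ``g`` (spectrum score ``s_g`` in [0, 1]) and each
    affected pair, the pair correlation follows
    ``rho_t = clip(base_corr + sfc_effect * s_g + a_g * sin(2 pi t / P + phi))``
    with amplitude ``a_g = base_amplitude + dfc_effect * s_g``, period ``P``
    drawn per subject-pair from ``modulation_period`` and a random phase.
    Unaffected ROIs are independent unit white Gaussian series.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = _make_covariates(config, rng)
    n_subj, n_roi, n_t = config.n_subjects, config.n_rois, config.n_timepoints
    scores = _group_scores(len(config.group_sizes))
    subj_score = np.repeat(scores, config.group_sizes)
    pairs = affected_pairs(config)
    t = np.arange(n_t, dtype=float)

    data = rng.standard_normal((n_subj, n_roi, n_t))
    for i in range(n_subj):
        s = subj_score[i]
        rho_level = config.base_corr + config.sfc_effect * s
        amp = config.base_amplitude + config.dfc_effect * s
        for a, b in pairs:
            period = rng.uniform(*config.modulation_period)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            rho_t = rho_level + amp * np.sin(2.0 * np.pi * t / period + phase)
            rho_t = np.clip(rho_t, -0.99, 0.99)
            z = rng.standard_normal(n_t)
            e = rng.standard_normal(n_t)
            data[i, a] = z
            data[i, b] = rho_t * z + np.sqrt(1.0 - rho_t**2) * e
    ts = ROITimeSeriesSet(
        data=data,
        subject_ids=labels.subject_ids,
        roi_ids=[f"ROI{j:03d}" for j in range(n_roi)],
    )
    return ts, labels
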