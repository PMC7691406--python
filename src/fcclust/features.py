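"""Connectivity feature extraction and covariate-adjusted selection.

Static functional connectivity (SFC) is the whole-series Pearson
correlation between two ROI time series.  Dynamic functional connectivity
(DFC) is characterised by the variance over time of sliding-window
Pearson correlations; windows overlap with a stride of one timepoint, and
the window length is chosen adaptively as the shortest length at which
windows of the series pass an augmented Dickey-Fuller stationarity
screen.  Candidate features (one per unordered ROI pair and measure) are
ranked by a mass-univariate covariate-adjusted group F-test
(``feature ~ group + age + gender + motion``) and the top-k smallest
p-values are retained.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats
from statsmodels.tsa.stattools import adfuller

from .containers import FeatureMatrix, GroupLabels, ROITimeSeriesSet

log = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """A series (or window) has zero variance, so correlation is undefined."""


@dataclass
class WindowSpec:
    """Sliding-window configuration.

    ``length`` fixes the window length outright; when ``None`` it is found
    adaptively via :func:`adf_window_length` over ``search_range``
    (inclusive, stepped by ``search_step``).  A candidate length is
    accepted when at least ``accept_frac`` of the windows of the series
    reject the unit-root null at level ``alpha``.  ``adf_maxlag`` is the
    lag order of the Dickey-Fuller regression (0 = no augmentation, the
    default — short windows leave no room for lagged differences).
    """

    length: int | None = None
    stride: int = 1
    alpha: float = 0.05
    search_range: tuple[int, int] = (20, 60)
    search_step: int = 5
    accept_frac: float = 0.80
    adf_maxlag: int = 0

    def __post_init__(self) -> None:
        if self.stride != 1:
            raise ValueError("stride is fixed at 1 timepoint")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        lo, hi = self.search_range
        if lo < 4 or hi < lo:
            raise ValueError("search_range must satisfy 4 <= min_len <= max_len")


@dataclass
class WindowLengthResult:
    length: int
    stationary: bool  # False when no candidate passed and max_len was returned


def static_fc(ts: ROITimeSeriesSet) -> np.ndarray:
    """Per-subject symmetric Pearson correlation matrices (subj x ROI x ROI)."""
    out = np.empty((ts.n_subjects, ts.n_rois, ts.n_rois))
    for i in range(ts.n_subjects):
        x = ts.data[i]
        sd = x.std(axis=1)
        if np.any(sd == 0):
            roi = ts.roi_ids[int(np.argmin(sd))]
            raise ZeroVarianceError(
                f"subject {ts.subject_ids[i]}: ROI {roi} has zero variance; "
                "Pearson correlation undefined"
            )
        out[i] = np.corrcoef(x)
    return out


def adf_window_length(x: np.ndarray, spec: WindowSpec | None = None) -> WindowLengthResult:
    """Smallest window length at which ``x`` looks window-wise stationary.

    Candidates ascend through ``spec.search_range``; for each, the ADF
    test (constant, no trend) is run on every window of that length, and
    the candidate is accepted when at least ``accept_frac`` of windows
    reject the unit-root null at ``alpha``.  Returns the largest candidate
    with ``stationary=False`` if none qualifies.
    """
    spec = spec or WindowSpec()
    x = np.asarray(x, dtype=float)
    lo, hi = spec.search_range
    if len(x) < lo:
        raise ValueError(f"series length {len(x)} below search range minimum {lo}")
    hi = min(hi, len(x))
    if np.ptp(x) == 0:
        raise ZeroVarianceError("constant series: stationarity test undefined")
    candidates = list(range(lo, hi + 1, spec.search_step))
    if candidates[-1] != hi:
        candidates.append(hi)
    for w in candidates:
        n_win = len(x) - w + 1
        max_failures = int(np.floor((1.0 - spec.accept_frac) * n_win))
        failures = 0
        ok = True
        for t0 in range(n_win):
            win = x[t0 : t0 + w]
            if np.ptp(win) == 0:
                p = 1.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = adfuller(win, maxlag=spec.adf_maxlag, regression="c", autolag=None)[1]
            if p >= spec.alpha:
                failures += 1
                if failures > max_failures:
                    ok = False
                    break
        if ok:
            return WindowLengthResult(length=w, stationary=True)
    return WindowLengthResult(length=candidates[-1], stationary=False)


def sliding_window_corr(x: np.ndarray, y: np.ndarray, w: int) -> np.ndarray:
    """Pearson correlation in overlapping windows of length ``w`` (stride 1).

    Output has length ``T - w + 1``; windows in which either series has
    zero variance yield NaN (flagged, excluded from downstream variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and equal length")
    if w < 2 or w > len(x):
        raise ValueError("window length must satisfy 2 <= w <= len(x)")
    xw = sliding_window_view(x, w)
    yw = sliding_window_view(y, w)
    xc = xw - xw.mean(axis=1, keepdims=True)
    yc = yw - yw.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    denom = sx * sy
    bad = denom == 0
    if np.any(bad):
        log.warning("%d window(s) with zero variance flagged as NaN", int(bad.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=1) / denom
    r[bad] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def dfc_variance(corr_series: np.ndarray) -> float:
    """Sample variance (ddof=1) of a windowed-correlation series."""
    r = np.asarray(corr_series, dtype=float)
    valid = r[np.isfinite(r)]
    if valid.size < 2:
        raise ValueError("need at least 2 valid windowed correlations")
    return float(np.var(valid, ddof=1))


def _covariate_design(labels: GroupLabels) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Reduced (covariates-only) and full (plus group dummies) design matrices."""
    cov = labels.covariates
    n = len(cov)
    x0 = np.column_stack(
        [np.ones(n), cov["age"].to_numpy(), cov["gender"].to_numpy(), cov["motion"].to_numpy()]
    )
    names = ["intercept", "age", "gender", "motion"]
    rank = 1
    for j in range(1, x0.shape[1]):
        new_rank = np.linalg.matrix_rank(x0[:, : j + 1])
        if new_rank == rank:
            raise ValueError(f"rank-deficient covariate design: {names[j]!r} is collinear")
        rank = new_rank
    codes = labels.codes()
    n_groups = codes.max() + 1
    dummies = np.zeros((n, n_groups - 1))
    for g in range(1, n_groups):
        dummies[codes == g, g - 1] = 1.0
    x1 = np.column_stack([x0, dummies])
    return x0, x1, names


def group_effect_pvalues(fm: FeatureMatrix, labels: GroupLabels) -> tuple[np.ndarray, np.ndarray]:
    """Covariate-adjusted group F-statistics and p-values for every feature.

    Mass-univariate ANCOVA: for each feature, the group term's partial
    F-test in ``feature ~ group + age + gender + motion``, computed for
    all features at once by projecting out the reduced and full designs.
    """
    if len(labels.labels) != fm.n_subjects:
        raise ValueError("labels and feature matrix disagree on subject count")
    codes = labels.codes()
    n_groups = codes.max() + 1
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    for g in range(n_groups):
        if np.sum(codes == g) < 2:
            raise ValueError("every group needs at least 2 subjects")
    x0, x1, _ = _covariate_design(labels)
    y = fm.values
    q0, _ = np.linalg.qr(x0)
    q1, _ = np.linalg.qr(x1)
    tot = (y**2).sum(axis=0)
    rss0 = tot - ((q0.T @ y) ** 2).sum(axis=0)
    rss1 = tot - ((q1.T @ y) ** 2).sum(axis=0)
    df_num = n_groups - 1
    df_den = fm.n_subjects - x1.shape[1]
    if df_den <= 0:
        raise ValueError("not enough subjects for the covariate-adjusted model")
    with np.errstate(invalid="ignore", divide="ignore"):
        f = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    f = np.where(np.isfinite(f), np.maximum(f, 0.0), np.inf)
    p = stats.f.sf(f, df_num, df_den)
    return f, p


def select_top_features(
    fm: FeatureMatrix,
    labels: GroupLabels,
    k: int,
    alpha_gate: float | None = None,
) -> tuple[FeatureMatrix, "pd.DataFrame"]:
    """Keep the ``k`` features with the smallest adjusted group p-values.

    Ties break by ascending feature index; selected columns are returned
    in ascending-p order.  ``alpha_gate`` optionally drops features whose
    p-value exceeds the gate even if ranked within the top k.  Also
    returns a table of F, p and rank for every candidate feature.
    """
    import pandas as pd

    if k > fm.n_features:
        raise ValueError(f"k={k} exceeds the number of candidate features {fm.n_features}")
    f, p = group_effect_pvalues(fm, labels)
    order = np.lexsort((np.arange(fm.n_features), p))
    ranks = np.empty(fm.n_features, dtype=int)
    ranks[order] = np.arange(1, fm.n_features + 1)
    table = pd.DataFrame(
        {"feature_id": fm.feature_ids, "F": f, "p": p, "rank": ranks}
    ).sort_values("rank", kind="stable").reset_index(drop=True)
    chosen = order[:k]
    if alpha_gate is not None:
        chosen = chosen[p[chosen] <= alpha_gate]
    return fm.select_columns(chosen), table


def upper_triangle_features(
    mats: np.ndarray, roi_ids: list[str], subject_ids: list[str], measure: str
) -> FeatureMatrix:
    """Vectorize the upper triangles of per-subject ROI x ROI matrices."""
    n_roi = mats.shape[1]
    iu = np.triu_indices(n_roi, 1)
    ids = [f"{roi_ids[a]}~{roi_ids[b]}|{measure}" for a, b in zip(*iu)]
    return FeatureMatrix(values=mats[:, iu[0], iu[1]], feature_ids=ids, subject_ids=subject_ids)


def _cohort_window_length(ts: ROITimeSeriesSet, spec: WindowSpec, max_series: int = 12) -> int:
    """One global window length: median of per-series adaptive lengths
    over a deterministic subsample of ROI series spread across subjects."""
    if spec.length is not None:
        return spec.length
    n = min(max_series, ts.n_subjects * ts.n_rois)
    subj_idx = np.linspace(0, ts.n_subjects - 1, n).round().astype(int)
    roi_idx = np.linspace(0, ts.n_rois - 1, n).round().astype(int)
    lengths = []
    for i, j in zip(subj_idx, roi_idx):
        lengths.append(adf_window_length(ts.data[i, j], spec).length)
    w = int(np.median(lengths))
    log.info("adaptive window length: %d (median over %d series)", w, n)
    return w


def dfc_variance_matrix(ts: ROITimeSeriesSet, w: int) -> np.ndarray:
    """Variance of sliding-window correlation for all ROI pairs
    (subjects x ROI x ROI), vectorized with windowed running sums."""
    n_subj, n_roi, n_t = ts.data.shape
    if w < 2 or w > n_t:
        raise ValueError("window length out of range")
    n_win = n_t - w + 1
    out = np.empty((n_subj, n_roi, n_roi))
    for i in range(n_subj):
        x = ts.data[i]
        # per-ROI windowed sums via cumulative sums
        c1 = np.concatenate([np.zeros((n_roi, 1)), np.cumsum(x, axis=1)], axis=1)
        c2 = np.concatenate([np.zeros((n_roi, 1)), np.cumsum(x**2, axis=1)], axis=1)
        s1 = c1[:, w:] - c1[:, :-w]                      # roi x win
        scatter = (c2[:, w:] - c2[:, :-w]) - s1**2 / w   # sum of sq deviations
        good = scatter > 0
        sd = np.sqrt(np.where(good, scatter, 1.0))
        # cross-product Gram matrix, updated window-to-window by rank-1 terms
        sum_r = np.zeros((n_roi, n_roi))
        sum_r2 = np.zeros((n_roi, n_roi))
        cnt = np.zeros((n_roi, n_roi))
        gram = x[:, :w] @ x[:, :w].T
        for t in range(n_win):
            if t > 0:
                gram += np.outer(x[:, t + w - 1], x[:, t + w - 1])
                gram -= np.outer(x[:, t - 1], x[:, t - 1])
            cov = gram - np.outer(s1[:, t], s1[:, t]) / w
            r = cov / np.outer(sd[:, t], sd[:, t])
            np.clip(r, -1.0, 1.0, out=r)
            valid = np.outer(good[:, t], good[:, t])
            if not valid.all():
                log.warning("window %d: zero-variance ROI(s); excluded from DFC", t)
                r = np.where(valid, r, 0.0)
            sum_r += r
            sum_r2 += r * r
            cnt += valid
        with np.errstate(invalid="ignore", divide="ignore"):
            var = (sum_r2 - sum_r**2 / cnt) / (cnt - 1)
        var[cnt < 2] = np.nan
        out[i] = np.maximum(var, 0.0)
    return out


def build_feature_matrices(
    ts: ROITimeSeriesSet,
    labels: GroupLabels,
    spec: WindowSpec | None = None,
    k: int = 100,
    fisher_z: bool = False,
) -> tuple[FeatureMatrix, FeatureMatrix, int]:
    """SFC and DFC-variance feature matrices after top-k selection.

    Returns ``(sfc_selected, dfc_selected, window_length)``.  With
    ``fisher_z`` the static correlations are arctanh-transformed before
    the group tests (off by default).
    """
    spec = spec or WindowSpec()
    sfc = static_fc(ts)
    w = _cohort_window_length(ts, spec)
    dfc = dfc_variance_matrix(ts, w)
    sfc_fm = upper_triangle_features(sfc, ts.roi_ids, ts.subject_ids, "SFC")
    if fisher_z:
        sfc_fm.values = np.arctanh(np.clip(sfc_fm.values, -1 + 1e-12, 1 - 1e-12))
    dfc_fm = upper_triangle_features(dfc, ts.roi_ids, ts.subject_ids, "DFCvar")
    # pairs with too few valid windows surface as NaN; treat as zero variance
    dfc_fm.values = np.nan_to_num(dfc_fm.values, nan=0.0)
    sfc_sel, _ = select_top_features(sfc_fm, labels, k)
    dfc_sel, _ = select_top_features(dfc_fm, labels, k)
    return sfc_sel, dfc_sel, w
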