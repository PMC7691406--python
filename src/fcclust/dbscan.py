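"""DBSCAN with k-distance initialization and epsilon-plot radius selection.

The clustering itself is the classical density-connectivity algorithm: a
*core point* has at least MinPts points (itself included) within radius
eps; clusters are maximal sets of density-connected points; non-core
points inside a core point's neighborhood are *border points* and attach
to the first cluster whose core point reaches them in scan order; all
remaining points are outliers (label 0).

Radius selection follows a two-stage recipe: an initial estimate from the
elbow of the k-distance graph, then DBSCAN evaluated over a grid of eps
values from zero to twice that estimate.  The number of clusters is
piecewise constant in eps; the widest step with at least two clusters is
taken as the most stable separation and its midpoint becomes the final
eps.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .containers import ClusteringResult, DensityParams

log = logging.getLogger(__name__)

_UNSEEN = -1


def _distances(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be 2-d (n x d)")
    return cdist(points, points)


def run_dbscan(points: np.ndarray, params: DensityParams) -> ClusteringResult:
    """Cluster ``points`` (n x d, Euclidean metric) at the given density.

    Clusters are numbered 1..K in discovery (scan) order; outliers get 0.
    """
    dist = _distances(points)
    n = dist.shape[0]
    neighbors = [np.flatnonzero(dist[i] <= params.eps) for i in range(n)]
    core = np.array([len(nb) >= params.min_pts for nb in neighbors])
    labels = np.full(n, _UNSEEN, dtype=int)
    cluster_id = 0
    for i in range(n):
        if labels[i] != _UNSEEN:
            continue
        if not core[i]:
            labels[i] = 0  # noise for now; may be claimed as border later
            continue
        cluster_id += 1
        labels[i] = cluster_id
        frontier = [i]
        while frontier:
            p = frontier.pop(0)
            for q in neighbors[p]:
                if labels[q] == _UNSEEN:
                    labels[q] = cluster_id
                    if core[q]:
                        frontier.append(q)
                elif labels[q] == 0 and not core[q]:
                    labels[q] = cluster_id  # border point claimed by first cluster
    return ClusteringResult(assignment=labels, params=params)


def k_distance_graph(points: np.ndarray, k: int) -> np.ndarray:
    """Distance from each point to its k-th nearest other point, sorted
    descending (the k-distance graph used to initialize eps)."""
    dist = _distances(points)
    n = dist.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of points {n}")
    srt = np.sort(dist, axis=1)  # column 0 is the self-distance 0
    return np.sort(srt[:, k])[::-1].copy()


def initial_eps_estimate(kdist: np.ndarray) -> float:
    """Automated elbow of the (descending) k-distance graph.

    Both axes are normalized to [0, 1] and the point with maximum
    perpendicular distance from the chord joining the endpoints is taken;
    its distance value is the estimate.  Ties (e.g. an exactly linear
    descent) break to the middle tied index.
    """
    d = np.asarray(kdist, dtype=float)
    if d.size < 3:
        raise ValueError("need at least 3 points for an elbow estimate")
    if np.all(d == 0):
        raise ValueError("all k-distances are zero: degenerate data")
    x = np.linspace(0.0, 1.0, d.size)
    span = d[0] - d[-1]
    y = (d - d[-1]) / span if span > 0 else np.zeros_like(d)
    # chord from (0, y0) to (1, y_end); perpendicular distance of each point
    x0, y0, x1, y1 = 0.0, y[0], 1.0, y[-1]
    num = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0)
    perp = num / np.hypot(y1 - y0, x1 - x0)
    best = perp.max()
    ties = np.flatnonzero(np.isclose(perp, best, rtol=0, atol=1e-12))
    idx = int(ties[len(ties) // 2])
    return float(d[idx])


@dataclass
class EpsilonPlot:
    """Number-of-clusters-vs-eps step plot and the chosen radius."""

    eps_grid: np.ndarray
    n_clusters_at: np.ndarray
    steps: list[tuple[float, float, int]]  # (eps_low, eps_high, n_clusters)
    chosen_eps: float
    chosen_step: int
    fallback: bool = False  # True when no step with >= 2 clusters existed


def _constant_runs(values: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index runs of equal consecutive values."""
    runs = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            runs.append((start, i - 1))
            start = i
    return runs


def epsilon_plot_select(
    points: np.ndarray,
    min_pts: int,
    eps_init: float,
    grid_size: int = 200,
) -> EpsilonPlot:
    """Evaluate DBSCAN over a uniform eps grid in (0, 2*eps_init] and pick
    the midpoint of the widest step with at least two clusters.

    Ties between equally wide steps break toward smaller eps.  If no step
    reaches two clusters the widest single-cluster step is used instead
    (with a warning).
    """
    if eps_init <= 0:
        raise ValueError("eps_init must be positive")
    if grid_size < 10:
        raise ValueError("grid_size must be at least 10")
    grid = 2.0 * eps_init * np.arange(1, grid_size + 1) / grid_size
    counts = np.empty(grid_size, dtype=int)
    for i, eps in enumerate(grid):
        counts[i] = run_dbscan(points, DensityParams(eps=eps, min_pts=min_pts)).n_clusters
    runs = _constant_runs(counts)
    steps = [(float(grid[a]), float(grid[b]), int(counts[a])) for a, b in runs]

    def widest(candidates: list[int]) -> int | None:
        best, best_w = None, -1.0
        for si in candidates:
            lo, hi, _ = steps[si]
            w = hi - lo
            if w > best_w:  # strict: ties keep the earlier (smaller-eps) step
                best, best_w = si, w
        return best

    multi = [i for i, s in enumerate(steps) if s[2] >= 2]
    fallback = False
    if multi:
        chosen = widest(multi)
    else:
        single = [i for i, s in enumerate(steps) if s[2] == 1]
        if not single:
            raise ValueError("no eps in the grid produced any cluster")
        log.warning("no eps range yielded >= 2 clusters; falling back to the 1-cluster step")
        chosen = widest(single)
        fallback = True
    lo, hi, _ = steps[chosen]
    return EpsilonPlot(
        eps_grid=grid,
        n_clusters_at=counts,
        steps=steps,
        chosen_eps=float((lo + hi) / 2.0),
        chosen_step=int(chosen),
        fallback=fallback,
    )


def auto_dbscan(
    points: np.ndarray, min_pts: int = 10, grid_size: int = 200
) -> tuple[ClusteringResult, EpsilonPlot]:
    """Full radius-selection pipeline: k-distance elbow (k = MinPts),
    epsilon-plot step search, then DBSCAN at the chosen eps."""
    kdist = k_distance_graph(points, min_pts)
    eps0 = initial_eps_estimate(kdist)
    plot = epsilon_plot_select(points, min_pts, eps0, grid_size=grid_size)
    result = run_dbscan(points, DensityParams(eps=plot.chosen_eps, min_pts=min_pts))
    return result, plot
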