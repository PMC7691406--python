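"""OPTICS ordering, reachability-plot cluster extraction, separation index.

OPTICS generalizes DBSCAN by ordering points rather than labelling them:
each point's *core distance* is the distance to its MinPts-th nearest
neighbor (the point itself counted, matching the DBSCAN core definition;
undefined when it exceeds the generating distance), and its *reachability*
is the smallest ``max(core_dist(s), dist(s, p))`` over already-processed
core points ``s``.  Valleys of the reachability plot are clusters;
thresholding the plot at ``t`` recovers exactly the DBSCAN partition of
core points at ``eps = t``.

The separation index scores how sharply a valley is delimited: for a
cluster bounded by peaks at ordering positions ``i`` and ``j``,

    S_k = mean(RP(i), RP(j)) / mean(RP(i+1), ..., RP(j-1)),

and the final index averages S_k over clusters.  Peaks are the
reachability values at cluster-opening boundary points; an undefined
(infinite) boundary value is replaced by the opposite peak.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import ClusteringResult, DensityParams
from .dbscan import _distances

log = logging.getLogger(__name__)

UNDEFINED = np.inf  # sentinel for undefined reachability / core distance


@dataclass
class ReachabilityProfile:
    """OPTICS output: ``reach[i]`` and ``core_dist[i]`` belong to the point
    ``ordering[i]``; the first ordered point always has undefined reach."""

    ordering: np.ndarray
    reach: np.ndarray
    core_dist: np.ndarray
    params: DensityParams

    def __post_init__(self) -> None:
        self.ordering = np.asarray(self.ordering, dtype=int)
        self.reach = np.asarray(self.reach, dtype=float)
        self.core_dist = np.asarray(self.core_dist, dtype=float)
        n = self.ordering.size
        if not np.array_equal(np.sort(self.ordering), np.arange(n)):
            raise ValueError("ordering must be a permutation of 0..n-1")
        if self.reach.shape != (n,) or self.core_dist.shape != (n,):
            raise ValueError("reach and core_dist must align with ordering")

    @property
    def n_points(self) -> int:
        return self.ordering.size


def run_optics(points: np.ndarray, params: DensityParams | None = None, min_pts: int = 15) -> ReachabilityProfile:
    """Classical OPTICS ordering with a seed list keyed by reachability.

    Without ``params`` the generating distance defaults to the maximum
    pairwise distance (always "large enough") with the given ``min_pts``.
    Ties in the seed queue break to the lowest point index, making the
    ordering deterministic.
    """
    dist = _distances(points)
    n = dist.shape[0]
    if params is None:
        gen = float(dist.max()) if n > 1 else 1.0
        params = DensityParams(eps=max(gen, np.finfo(float).tiny), min_pts=min_pts)
    # core distance: MinPts-th nearest neighbor counting the point itself
    if params.min_pts <= n:
        kth = np.sort(dist, axis=1)[:, params.min_pts - 1]
    else:
        kth = np.full(n, np.inf)
    core_dist = np.where(kth <= params.eps, kth, UNDEFINED)

    processed = np.zeros(n, dtype=bool)
    current_reach = np.full(n, UNDEFINED)
    in_seeds = np.zeros(n, dtype=bool)
    ordering: list[int] = []
    reach_out: list[float] = []
    core_out: list[float] = []

    def pop_next() -> int:
        if in_seeds.any():
            cand = np.flatnonzero(in_seeds)
            # smallest reachability, ties to lowest index (cand is ascending)
            p = int(cand[np.argmin(current_reach[cand])])
            in_seeds[p] = False
            return p
        return int(np.flatnonzero(~processed)[0])

    while not processed.all():
        p = pop_next()
        processed[p] = True
        ordering.append(p)
        reach_out.append(float(current_reach[p]))
        core_out.append(float(core_dist[p]))
        if np.isfinite(core_dist[p]):
            nbrs = np.flatnonzero((dist[p] <= params.eps) & ~processed)
            new_reach = np.maximum(core_dist[p], dist[p, nbrs])
            better = new_reach < current_reach[nbrs]
            upd = nbrs[better]
            current_reach[upd] = new_reach[better]
            in_seeds[upd] = True
    return ReachabilityProfile(
        ordering=np.array(ordering),
        reach=np.array(reach_out),
        core_dist=np.array(core_out),
        params=params,
    )


def extract_clusters(profile: ReachabilityProfile, threshold: float) -> ClusteringResult:
    """Threshold the reachability plot: a point with reach above the
    threshold opens a new cluster if it is core at the threshold,
    otherwise it is an outlier; points with reach at or below the
    threshold join the current cluster.  Labels align with the original
    point indices (0 = outlier)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = profile.n_points
    labels = np.zeros(n, dtype=int)
    cluster_id = 0
    current = 0
    for pos in range(n):
        point = profile.ordering[pos]
        r = profile.reach[pos]
        c = profile.core_dist[pos]
        if r > threshold:
            if c <= threshold:
                cluster_id += 1
                current = cluster_id
                labels[point] = current
            else:
                labels[point] = 0
                current = 0
        else:
            if current == 0:  # reachable run with no open cluster: open one
                cluster_id += 1
                current = cluster_id
            labels[point] = current
    # renumber to contiguous 1..K in discovery order (drop empty ids, if any)
    kept = [cid for cid in range(1, cluster_id + 1) if np.any(labels == cid)]
    remap = {cid: i + 1 for i, cid in enumerate(kept)}
    labels = np.array([remap.get(l, 0) for l in labels])
    return ClusteringResult(
        assignment=labels,
        params=DensityParams(eps=threshold, min_pts=profile.params.min_pts),
    )


def auto_threshold(profile: ReachabilityProfile, rule: str = "max_clusters") -> float:
    """Data-driven extraction threshold from the reachability plot.

    ``max_clusters`` (default) evaluates every distinct threshold regime
    (the intervals between consecutive sorted reachability/core-distance
    values), finds the maximal count of substantial clusters (at least
    MinPts members) among regimes that keep at least half the points
    clustered, and returns the midpoint of the widest threshold interval
    achieving it — the most stable cut that separates every peak from
    every valley, even when valley depths differ between clusters.
    ``widest_gap`` returns the midpoint of the single widest gap in the
    sorted reachability values; it is simpler but can land between two
    peak heights when cluster densities are very unequal.
    """
    reach = profile.reach[np.isfinite(profile.reach)]
    if reach.size < 2:
        raise ValueError("need at least 2 defined reachability values")
    if np.unique(reach).size < 2:
        raise ValueError("all reachability values equal; supply a manual threshold")
    if rule == "widest_gap":
        srt = np.sort(reach)
        g = int(np.argmax(np.diff(srt)))
        return float((srt[g] + srt[g + 1]) / 2.0)
    if rule != "max_clusters":
        raise ValueError("rule must be 'max_clusters' or 'widest_gap'")
    core = profile.core_dist[np.isfinite(profile.core_dist)]
    breaks = np.unique(np.concatenate([reach, core]))
    breaks = breaks[breaks >= 0]
    mids = (breaks[:-1] + breaks[1:]) / 2.0
    keep = mids > 0
    mids, lo, hi = mids[keep], breaks[:-1][keep], breaks[1:][keep]

    def substantial_clusters(t: float) -> tuple[int, float]:
        # clusters below MinPts members are ordering artifacts, not
        # density clusters (a core point alone implies MinPts neighbors)
        res = extract_clusters(profile, t)
        sizes = np.bincount(res.assignment)[1:]
        big = sizes >= profile.params.min_pts
        coverage = sizes[big].sum() / profile.n_points
        return int(big.sum()), float(coverage)

    scored = [substantial_clusters(float(t)) for t in mids]
    raw_counts = np.array([k for k, _ in scored])
    coverage = np.array([c for _, c in scored])
    # prefer the richest structure that still accounts for (nearly) the
    # whole cohort; relax the coverage bar only if nothing meets it
    counts = np.full_like(raw_counts, -1)
    for bar in (0.9, 0.5, 0.0):
        ok = coverage >= bar
        if ok.any() and raw_counts[ok].max() >= 1:
            counts[ok] = raw_counts[ok]
            break
    k_max = counts.max()
    if k_max < 1:
        raise ValueError("no threshold extracts any cluster; supply one manually")
    best = None  # (width, interval_lo, interval_hi)
    i = 0
    while i < len(mids):
        if counts[i] == k_max:
            j = i
            while j + 1 < len(mids) and counts[j + 1] == k_max:
                j += 1
            width = hi[j] - lo[i]
            if best is None or width > best[0]:
                best = (width, lo[i], hi[j])
            i = j + 1
        else:
            i += 1
    return float((best[1] + best[2]) / 2.0)


@dataclass
class SeparationIndexResult:
    per_cluster: list[tuple[int, float]]
    mean_index: float


def separation_index(
    profile: ReachabilityProfile, clusters: ClusteringResult
) -> SeparationIndexResult:
    """Peak-to-valley ratio for each cluster's reachability valley.

    A cluster occupies a contiguous run of the ordering.  Its left peak
    is its opening point; its right peak is the next cluster's opening
    point (for the last cluster, the first position past the run if one
    exists).  Valley values are the reachabilities strictly between the
    peaks.  Undefined peak values (the start of the plot) fall back to
    the opposite peak; clusters with an empty valley are skipped.
    """
    ord_labels = clusters.assignment[profile.ordering]
    starts: list[tuple[int, int]] = []  # (position, cluster id)
    seen: set[int] = set()
    for pos, lab in enumerate(ord_labels):
        if lab > 0 and lab not in seen:
            seen.add(lab)
            starts.append((pos, int(lab)))
    if not starts:
        raise ValueError("no clusters to score")
    n = profile.n_points
    per: list[tuple[int, float]] = []
    for idx, (i, cid) in enumerate(starts):
        if idx + 1 < len(starts):
            j = starts[idx + 1][0]
        else:
            run_end = int(np.max(np.flatnonzero(ord_labels == cid)))
            j = run_end + 1 if run_end + 1 < n else None
        if j is None:
            j_val = None
        else:
            j_val = profile.reach[j]
        i_val = profile.reach[i]
        peaks = [v for v in (i_val, j_val) if v is not None and np.isfinite(v)]
        if not peaks:
            log.warning("cluster %d: no defined bounding peak; skipped", cid)
            continue
        if j_val is None or not np.isfinite(j_val) or not np.isfinite(i_val):
            log.info("cluster %d: undefined boundary peak replaced by opposite peak", cid)
        left = i_val if np.isfinite(i_val) else peaks[0]
        right = j_val if (j_val is not None and np.isfinite(j_val)) else peaks[0]
        valley_end = j if j is not None else n
        valley = profile.reach[i + 1 : valley_end]
        valley = valley[np.isfinite(valley)]
        if valley.size == 0:
            log.warning("cluster %d: empty valley; skipped", cid)
            continue
        s_k = float(((left + right) / 2.0) / valley.mean())
        per.append((cid, s_k))
    if not per:
        raise ValueError("no cluster had a non-empty valley with defined peaks")
    mean_index = float(np.mean([s for _, s in per]))
    return SeparationIndexResult(per_cluster=per, mean_index=mean_index)
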