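"""Cluster purity against diagnostic group labels.

Clusters are matched one-to-one to groups by maximizing total agreement
on the contingency table (optimal bipartite assignment); a greedy
majority matcher is available for sensitivity analysis.  Overall purity
is the percentage of subjects whose assigned cluster maps to their true
group, with outliers (label 0) in the denominator and never counted as
correct.  Per-group success rates are each group's members captured by
its matched cluster, as a percentage of the full group size.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import ClusteringResult, GroupLabels

log = logging.getLogger(__name__)


@dataclass
class PurityReport:
    overall_purity: float                  # percent
    per_group: list[tuple[str, float]]     # (group, success rate percent)
    matching: dict[int, str]               # cluster id -> group name
    n_outliers: int
    n_clusters: int

    @property
    def group_mean(self) -> float:
        """Column-style summary: mean of the per-group success rates."""
        return float(np.mean([r for _, r in self.per_group]))


def _contingency(pred: ClusteringResult, truth: GroupLabels) -> tuple[np.ndarray, list[str]]:
    if pred.assignment.size != truth.n_subjects:
        raise ValueError("clustering and labels disagree on subject count")
    groups = truth.group_names
    codes = truth.codes()
    table = np.zeros((pred.n_clusters, len(groups)), dtype=int)
    for cid in range(1, pred.n_clusters + 1):
        members = codes[pred.assignment == cid]
        for g in range(len(groups)):
            table[cid - 1, g] = int(np.sum(members == g))
    return table, groups


def match_clusters_to_groups(
    pred: ClusteringResult, truth: GroupLabels, greedy: bool = False
) -> dict[int, str]:
    """One-to-one cluster-to-group matching maximizing total agreement.

    With more clusters than groups the extra clusters stay unmatched;
    with fewer, some groups get no cluster.  ``greedy`` switches to
    majority-vote matching (largest contingency cells first).
    """
    if pred.n_clusters == 0:
        raise ValueError("no clusters to match")
    table, groups = _contingency(pred, truth)
    matching: dict[int, str] = {}
    if greedy:
        used_c: set[int] = set()
        used_g: set[int] = set()
        order = np.dstack(np.unravel_index(np.argsort(-table, axis=None), table.shape))[0]
        for c, g in order:
            if c not in used_c and g not in used_g and table[c, g] > 0:
                matching[int(c) + 1] = groups[int(g)]
                used_c.add(int(c))
                used_g.add(int(g))
    else:
        rows, cols = linear_sum_assignment(-table)
        for c, g in zip(rows, cols):
            if table[c, g] > 0:
                matching[int(c) + 1] = groups[int(g)]
    return matching


def purity(pred: ClusteringResult, truth: GroupLabels, greedy: bool = False) -> PurityReport:
    """Purity report in the group-by-group success-rate layout."""
    matching = match_clusters_to_groups(pred, truth, greedy=greedy)
    groups = truth.group_names
    if pred.n_clusters != len(groups):
        log.warning(
            "number of clusters (%d) differs from number of groups (%d); "
            "unmatched clusters score nothing and unmatched groups score 0%%",
            pred.n_clusters, len(groups),
        )
    labels = np.array(truth.labels)
    correct = 0
    per_group: list[tuple[str, float]] = []
    group_to_cluster = {g: c for c, g in matching.items()}
    for g in groups:
        size = int(np.sum(labels == g))
        cid = group_to_cluster.get(g)
        hits = 0
        if cid is not None:
            hits = int(np.sum((pred.assignment == cid) & (labels == g)))
        correct += hits
        per_group.append((g, 100.0 * hits / size))
    overall = 100.0 * correct / truth.n_subjects
    return PurityReport(
        overall_purity=float(overall),
        per_group=per_group,
        matching=matching,
        n_outliers=pred.n_outliers,
        n_clusters=pred.n_clusters,
    )
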