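"""Scoring latent variables against diagnosis labels.

The headline classification metric is an ROC curve built from a two-cluster
k-means partition of a single latent variable: starting from the exact
two-cluster solution, samples are relocated one at a time — always the move
that minimally increases the k-means objective — until one cluster empties,
recording the true/false positive fractions after every move; the sweep is
run in both directions and the union of recorded points gives the curve.
Partition agreement is additionally measured with the split-join distance,
and group differences on a latent variable with the (unpaired) Mann-Whitney
rank-sum test.

k-means on one dimension is solved exactly by enumerating the n-1 sorted
split points, so the metric has no seed sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

#: diagnosis labels counted as the positive class by default
DEFAULT_POSITIVE_LABELS = frozenset({"RRMS", "CIS", "RIS"})


@dataclass(frozen=True)
class Partition:
    """Assignment of each sample to cluster 1 or 2."""

    assignment: pd.Series  # values in {1, 2}

    def __post_init__(self):
        vals = set(self.assignment.unique().tolist())
        if not vals <= {1, 2}:
            raise ValueError(f"cluster ids must be 1 or 2, got {sorted(vals)}")

    def members(self, cluster: int) -> list:
        return list(self.assignment[self.assignment == cluster].index)

    def as_sets(self) -> list[set]:
        return [set(self.members(c)) for c in (1, 2) if self.members(c)]


@dataclass(frozen=True)
class ROCResult:
    """Ordered (FPR, TPR) points and the trapezoidal area under them."""

    points: np.ndarray  # (m, 2), sorted by (FPR, TPR), from (0,0) to (1,1)
    auc: float
    positive_class: str = "positive"


def _as_series(values) -> pd.Series:
    if isinstance(values, pd.Series):
        return values.astype(float)
    arr = np.asarray(values, dtype=float)
    return pd.Series(arr, index=range(len(arr)))


def _objective(values: np.ndarray, in_one: np.ndarray) -> float:
    """Total within-cluster sum of squared deviations from cluster means."""
    total = 0.0
    for mask in (in_one, ~in_one):
        if mask.any():
            v = values[mask]
            total += float(((v - v.mean()) ** 2).sum())
    return total


def kmeans_1d(values, k: int = 2) -> tuple[Partition, float]:
    """Exact two-cluster k-means of a 1-D variable.

    Enumerates the n-1 split points of the sorted values and returns the
    partition minimizing the within-cluster sum of squares.  Cluster 1 is
    the lower-mean cluster.
    """
    if k != 2:
        raise ValueError("only k = 2 is supported")
    s = _as_series(values)
    v = s.to_numpy()
    if len(v) < 2 or np.unique(v).size < 2:
        raise ValueError("need at least 2 distinct values")
    order = np.argsort(v, kind="mergesort")
    sv = v[order]
    csum = np.concatenate([[0.0], np.cumsum(sv)])
    csq = np.concatenate([[0.0], np.cumsum(sv**2)])
    n = len(sv)

    def seg_ss(i, j):  # within-SS of sv[i:j]
        m = j - i
        su = csum[j] - csum[i]
        return (csq[j] - csq[i]) - su * su / m

    best_i, best_obj = None, np.inf
    for i in range(1, n):
        obj = seg_ss(0, i) + seg_ss(i, n)
        if obj < best_obj - 1e-15:
            best_i, best_obj = i, obj
    assign = pd.Series(2, index=s.index, dtype=int)
    assign.iloc[order[:best_i]] = 1
    return Partition(assignment=assign), float(max(best_obj, 0.0))


def split_join_distance(a: Partition | Mapping, b: Partition | Mapping) -> int:
    """Split-join distance between two partitions of the same samples.

    d = (n - sum_i max_j |A_i & B_j|) + (n - sum_j max_i |B_j & A_i|);
    the number of element moves needed to turn each partition into a common
    refinement, summed over both directions.
    """
    sa = a.as_sets() if isinstance(a, Partition) else _sets_from_mapping(a)
    sb = b.as_sets() if isinstance(b, Partition) else _sets_from_mapping(b)
    ua = set().union(*sa)
    ub = set().union(*sb)
    if ua != ub:
        raise ValueError("partitions cover different sample universes")
    n = len(ua)
    d1 = n - sum(max(len(ai & bj) for bj in sb) for ai in sa)
    d2 = n - sum(max(len(bj & ai) for ai in sa) for bj in sb)
    return int(d1 + d2)


def _sets_from_mapping(m: Mapping) -> list[set]:
    groups: dict = {}
    for k, v in m.items():
        groups.setdefault(v, set()).add(k)
    return list(groups.values())


def label_partition(labels: pd.Series, positive_labels=DEFAULT_POSITIVE_LABELS) -> Partition:
    """Two-block partition induced by positive-class membership."""
    pos = labels.isin(set(positive_labels))
    assign = pd.Series(np.where(pos, 2, 1), index=labels.index, dtype=int)
    return Partition(assignment=assign)


# --------------------------------------------------------------------------
# relocation ROC
# --------------------------------------------------------------------------

def auroc_by_relocation(values, is_positive) -> ROCResult:
    """ROC curve by minimal-cost sample relocation between two k-means clusters.

    Procedure: (1) exact k = 2 clustering of the latent variable; (2) the
    true-positive cluster is the one holding the larger fraction of the
    positive class; (3) sweep A repeatedly relocates, from cluster 1 to
    cluster 2, the sample whose move minimally increases the live k-means
    objective, recording (FPR, TPR) after each move until cluster 1 empties;
    (4) the clustering is reinstated and sweep B runs symmetrically from
    cluster 2 to cluster 1; (5) the curve is the union of all recorded points
    plus (0,0) and (1,1), sorted by (FPR, TPR), with trapezoidal AUC.

    Ties in the minimal objective increase are broken by the smaller sample
    position.
    """
    s = _as_series(values)
    pos = np.asarray(pd.Series(is_positive, index=s.index).astype(bool))
    v = s.to_numpy()
    n_pos = int(pos.sum())
    n_ctl = int((~pos).sum())
    if n_pos == 0 or n_ctl == 0:
        raise ValueError("both classes must be present")

    part, _ = kmeans_1d(s)
    in_one0 = (part.assignment.to_numpy() == 1)

    # step 3: true-positive cluster by detected positive-class fraction
    r_pos_c1 = pos[in_one0].sum() / n_pos
    r_ctl_c1 = (~pos)[in_one0].sum() / n_ctl
    tp_is_cluster_one = r_pos_c1 > r_ctl_c1

    def point(in_one: np.ndarray) -> tuple[float, float]:
        pred = in_one if tp_is_cluster_one else ~in_one
        return (float((~pos)[pred].sum() / n_ctl), float(pos[pred].sum() / n_pos))

    points = {point(in_one0)}

    for from_one in (True, False):  # sweep A then sweep B
        in_one = in_one0.copy()
        while True:
            src = np.flatnonzero(in_one == from_one)
            if src.size == 0:
                break
            best_idx, best_obj = None, np.inf
            for i in src:
                trial = in_one.copy()
                trial[i] = not from_one
                obj = _objective(v, trial)
                if obj < best_obj - 1e-15:
                    best_idx, best_obj = i, obj
            in_one[best_idx] = not from_one
            points.add(point(in_one))

    points.add((0.0, 0.0))
    points.add((1.0, 1.0))
    pts = np.array(sorted(points))
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return ROCResult(points=pts, auc=auc)


# --------------------------------------------------------------------------
# rank-sum test
# --------------------------------------------------------------------------

def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test for two independent samples.

    Exact enumeration when m + n <= 12 and there are no ties; otherwise the
    normal approximation with tie and continuity correction.  Returns the
    U statistic of ``x`` and the two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# component table
# --------------------------------------------------------------------------

def evaluate_components(
    results,
    labels: pd.Series | None = None,
    components: Iterable[int] | None = None,
    positive_labels=DEFAULT_POSITIVE_LABELS,
) -> pd.DataFrame:
    """AUROC and split-join of each latent variable against the labels.

    One row per component with the relocation AUROC, the split-join distance
    between the exact two-cluster partition and the label partition, and a
    ``best`` flag on the maximal-AUROC component (ties to the lower index).
    """
    if labels is None:
        labels = results.labels
    if labels is None:
        raise ValueError("no labels on the results; pass them explicitly")
    labels = labels.reindex(results.sample_ids)
    if components is None:
        components = range(1, min(10, results.n_components) + 1)
    components = [c for c in components if 1 <= c <= results.n_components]
    truth = label_partition(labels, positive_labels)
    pos = labels.isin(set(positive_labels))

    rows = []
    for c in components:
        scores = results.global_scores[f"L{c}"]
        roc = auroc_by_relocation(scores, pos)
        part, _ = kmeans_1d(scores)
        rows.append({"component": c, "auc": roc.auc,
                     "split_join": split_join_distance(part, truth)})
    table = pd.DataFrame(rows)
    best = int(table["auc"].idxmax())  # idxmax takes the first maximum
    table["best"] = False
    table.loc[best, "best"] = True
    return table
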