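"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most direct route available —
exhaustive enumeration, closed form, or a structurally different numerical
path — and is kept deliberately separate from the package implementation it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import eigh


# --------------------------------------------------------------------------
# multi-block co-inertia: literal five-step reference decomposition
# --------------------------------------------------------------------------

def mcia_reference(block_mats: list[np.ndarray], n_components: int):
    """Direct implementation of the per-component decomposition.

    Works on already-standardized block matrices.  Uses an eigendecomposition
    of the n x n Gram matrix (not an SVD of the concatenated matrix) to get
    the leading triplet, then splits, renormalizes, and deflates each block
    by its own loading.  Returns (global_scores, loadings_per_block,
    eigenvalues, raw_weights).
    """
    mats = [m.astype(float).copy() for m in block_mats]
    n = mats[0].shape[0]
    sizes = [m.shape[1] for m in mats]
    scores = np.zeros((n, n_components))
    eigs = np.zeros(n_components)
    loadings = [np.zeros((p, n_components)) for p in sizes]
    weights = np.zeros((sum(sizes), n_components))
    for c in range(n_components):
        x = np.concatenate(mats, axis=1)
        gram = x @ x.T
        vals, vecs = eigh(gram)
        lam, u = vals[-1], vecs[:, -1]
        s = np.sqrt(max(lam, 0.0))
        v = x.T @ u / s if s > 0 else np.zeros(x.shape[1])
        if v[np.argmax(np.abs(v))] < 0:
            u, v = -u, -v
        scores[:, c] = u * s
        eigs[c] = s**2
        weights[:, c] = v
        off = 0
        for i, m in enumerate(mats):
            seg = v[off:off + sizes[i]]
            off += sizes[i]
            norm = np.linalg.norm(seg)
            vk = seg / norm if norm > 1e-10 else np.zeros_like(seg)
            loadings[i][:, c] = vk
            mats[i] = m - np.outer(m @ vk, vk)
    return scores, loadings, eigs, weights


# --------------------------------------------------------------------------
# 1-D k-means: Lloyd's algorithm with exhaustive restarts
# --------------------------------------------------------------------------

def lloyd_kmeans_1d(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Best two-cluster solution over Lloyd runs from every center pair."""
    v = np.asarray(values, float)
    uniq = np.unique(v)
    best_assign, best_obj = None, np.inf
    for c1, c2 in itertools.combinations(uniq, 2):
        centers = np.array([c1, c2])
        for _ in range(100):
            assign = np.argmin(np.abs(v[:, None] - centers[None, :]), axis=1)
            new = np.array([v[assign == j].mean() if (assign == j).any() else centers[j]
                            for j in (0, 1)])
            if np.allclose(new, centers):
                break
            centers = new
        obj = sum(((v[assign == j] - v[assign == j].mean()) ** 2).sum()
                  for j in (0, 1) if (assign == j).any())
        if obj < best_obj - 1e-12:
            best_obj, best_assign = obj, assign
    # orient: cluster 1 = lower mean
    m0 = v[best_assign == 0].mean()
    m1 = v[best_assign == 1].mean() if (best_assign == 1).any() else np.inf
    out = np.where(best_assign == (0 if m0 < m1 else 1), 1, 2)
    return out, float(best_obj)


# --------------------------------------------------------------------------
# relocation ROC: stepwise exhaustive-move oracle
# --------------------------------------------------------------------------

def _wcss(v: np.ndarray, in_one: np.ndarray) -> float:
    tot = 0.0
    for mask in (in_one, ~in_one):
        if mask.any():
            tot += float(((v[mask] - v[mask].mean()) ** 2).sum())
    return tot


def relocation_roc_reference(values: np.ndarray, is_pos: np.ndarray):
    """Literal step-by-step relocation curve, evaluating every candidate move.

    Initial partition by exhaustive split enumeration; at every step all
    candidate relocations are evaluated and the minimal-objective move taken
    (ties to the smallest index); both sweep directions are run from the
    reinstated clustering and the union of points (with the endpoints) is
    returned together with the trapezoidal area.
    """
    v = np.asarray(values, float)
    pos = np.asarray(is_pos, bool)
    n = len(v)
    order = np.argsort(v, kind="mergesort")
    best_obj, best_mask = np.inf, None
    for i in range(1, n):
        mask = np.zeros(n, bool)
        mask[order[:i]] = True
        obj = _wcss(v, mask)
        if obj < best_obj - 1e-15:
            best_obj, best_mask = obj, mask
    in_one0 = best_mask
    n_pos, n_ctl = pos.sum(), (~pos).sum()
    tp_is_one = (pos[in_one0].sum() / n_pos) > ((~pos)[in_one0].sum() / n_ctl)

    def pt(in_one):
        pred = in_one if tp_is_one else ~in_one
        return (float((~pos)[pred].sum() / n_ctl), float(pos[pred].sum() / n_pos))

    pts = {pt(in_one0), (0.0, 0.0), (1.0, 1.0)}
    for direction in (True, False):
        in_one = in_one0.copy()
        while (in_one == direction).any():
            cands = np.flatnonzero(in_one == direction)
            objs = []
            for i in cands:
                trial = in_one.copy()
                trial[i] = not direction
                objs.append(_wcss(v, trial))
            move = cands[int(np.argmin(objs))]
            in_one[move] = not direction
            pts.add(pt(in_one))
    arr = np.array(sorted(pts))
    auc = float(np.trapezoid(arr[:, 1], arr[:, 0]))
    return arr, auc


# --------------------------------------------------------------------------
# split-join distance via explicit overlap table
# --------------------------------------------------------------------------

def split_join_reference(sets_a: list[set], sets_b: list[set]) -> int:
    n = sum(len(s) for s in sets_a)
    overlap = [[len(a & b) for b in sets_b] for a in sets_a]
    d_ab = n - sum(max(row) for row in overlap)
    d_ba = n - sum(max(overlap[i][j] for i in range(len(sets_a)))
                   for j in range(len(sets_b)))
    return d_ab + d_ba


# --------------------------------------------------------------------------
# exact rank-sum p by enumerating all group assignments
# --------------------------------------------------------------------------

def rank_sum_exact_reference(x, y) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p over all C(m+n, m) label arrangements."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    m, n = len(x), len(y)
    pooled = np.concatenate([x, y])

    def u_stat(ix):
        xs = pooled[list(ix)]
        ys = np.delete(pooled, list(ix))
        return sum((xi > ys).sum() + 0.5 * (xi == ys).sum() for xi in xs)

    u_obs = u_stat(range(m))
    mu = m * n / 2.0
    count = total = 0
    for ix in itertools.combinations(range(m + n), m):
        total += 1
        if abs(u_stat(ix) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return float(u_obs), count / total


# --------------------------------------------------------------------------
# soft-threshold closed form for orthonormal lasso designs
# --------------------------------------------------------------------------

def soft_threshold(b: np.ndarray, lam: float) -> np.ndarray:
    return np.sign(b) * np.maximum(np.abs(b) - lam, 0.0)


def orthonormal_design(n: int, p: int, rng: np.random.Generator) -> np.ndarray:
    """Mean-zero columns with population SD 1 and X'X = n I."""
    x = rng.normal(size=(n, p))
    x -= x.mean(axis=0)
    q, _ = np.linalg.qr(x)
    return q[:, :p] * np.sqrt(n)
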