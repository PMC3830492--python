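"""Average-linkage hierarchical clustering of gene expression profiles.

Reproduces the Cluster 3.0 procedure: genes are rows, their log2-ratio
profiles are compared by correlation distance (1 − Pearson r, centered by
default; the uncentered variant — Cluster 3.0's historical default — is
selectable), and clusters are agglomerated by unweighted average linkage
(UPGMA).  Tie-breaking is deterministic: among equally close pairs the
lexicographically smallest (i, j) merges first, so results are bit-exact
across runs and row permutations only relabel leaves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClusterTree",
    "distance_matrix",
    "average_linkage",
    "order_leaves",
]


@dataclass
class ClusterTree:
    """Result of an agglomerative clustering.

    ``merges`` lists n−1 merge events as (left, right, distance) with
    cluster ids: leaves are 0..n−1 in input order, internal node i of the
    j-th merge gets id n−1+j.
    """

    n_leaves: int
    merges: list[tuple[int, int, float]]

    def children(self) -> dict[int, tuple[int, int]]:
        return {
            self.n_leaves + j: (left, right)
            for j, (left, right, _d) in enumerate(self.merges)
        }


def _pearson(u: np.ndarray, v: np.ndarray, centered: bool) -> float:
    if centered:
        u = u - u.mean()
        v = v - v.mean()
    denom = np.sqrt((u * u).sum() * (v * v).sum())
    if denom == 0:
        return 0.0  # constant profile: no linear relation measurable
    return float((u * v).sum() / denom)


def distance_matrix(
    profiles: pd.DataFrame, metric: str = "correlation", max_missing: float = 0.5
) -> tuple[np.ndarray, pd.DataFrame]:
    """Pairwise correlation distances between gene profiles.

    ``profiles`` has one row per gene (``gene_id`` column plus numeric
    profile columns; missing values allowed).  ``metric`` is
    ``"correlation"`` (1 − centered Pearson r) or ``"correlation_uncentered"``.
    Missing values are handled pairwise-complete; genes missing more than
    ``max_missing`` of their values are dropped with a warning.  Returns the
    distance matrix and the (possibly reduced) profile table it refers to.
    """
    if metric not in ("correlation", "correlation_uncentered"):
        raise ValueError(f"unknown metric {metric!r}")
    value_cols = [c for c in profiles.columns if c != "gene_id"]
    X = profiles[value_cols].to_numpy(float)
    frac_missing = np.isnan(X).mean(axis=1)
    keep = frac_missing <= max_missing
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} profiles with > {max_missing:.0%} missing "
            "values dropped",
            stacklevel=2,
        )
        profiles = profiles[keep].reset_index(drop=True)
        X = X[keep]
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 profiles")
    centered = metric == "correlation"
    D = np.zeros((n, n))
    finite = ~np.isnan(X)
    for i in range(n):
        for j in range(i + 1, n):
            both = finite[i] & finite[j]
            if both.sum() < 2:
                gi, gj = profiles["gene_id"].iloc[i], profiles["gene_id"].iloc[j]
                raise ValueError(
                    f"profiles {gi!r} and {gj!r} share fewer than 2 values"
                )
            r = _pearson(X[i, both], X[j, both], centered)
            D[i, j] = D[j, i] = 1.0 - r
    return D, profiles


def average_linkage(dist: np.ndarray) -> ClusterTree:
    """UPGMA agglomeration of a symmetric distance matrix.

    At every step the closest pair of clusters merges; the new cluster's
    distance to any other is the unweighted average over all member pairs
    (Lance–Williams update with size weights).  Ties merge the pair with
    the lexicographically smallest active (i, j).
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 leaves")
    work = D.astype(float).copy()
    np.fill_diagonal(work, np.inf)
    active = list(range(n))  # row index in `work` → active; always sorted
    ids = list(range(n))  # cluster id carried by each row
    sizes = [1] * n
    alive = np.ones(n, dtype=bool)
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        sub = work[np.ix_(alive, alive)]
        flat = int(np.argmin(sub))  # row-major argmin → lexicographically
        m = sub.shape[0]  # smallest (i, j) among ties
        ai, aj = divmod(flat, m)
        idx = np.flatnonzero(alive)
        i, j = int(idx[ai]), int(idx[aj])
        if i > j:
            i, j = j, i
        d = work[i, j]
        lo, hi = sorted((ids[i], ids[j]))
        merges.append((lo, hi, float(d)))
        # unweighted average of member-pair distances
        ni, nj = sizes[i], sizes[j]
        newrow = (ni * work[i] + nj * work[j]) / (ni + nj)
        work[i, :] = newrow
        work[:, i] = newrow
        work[i, i] = np.inf
        alive[j] = False
        work[j, :] = np.inf
        work[:, j] = np.inf
        ids[i] = n + step
        sizes[i] = ni + nj
    return ClusterTree(n_leaves=n, merges=merges)


def order_leaves(tree: ClusterTree, profiles: pd.DataFrame) -> list[int]:
    """Deterministic heat-map display order.

    At every internal node the subtree with the smaller mean profile value
    is placed first; ties keep the merge's (left, right) order.  Returns
    leaf indices (row positions in ``profiles``).
    """
    value_cols = [c for c in profiles.columns if c != "gene_id"]
    X = profiles[value_cols].to_numpy(float)
    n = tree.n_leaves
    if len(X) != n:
        raise ValueError("profiles must match tree leaves 1:1")
    children = tree.children()

    def collect(node: int) -> list[int]:
        if node < n:
            return [node]
        left, right = children[node]
        lo, ro = collect(left), collect(right)
        lmean = np.nanmean(X[lo])
        rmean = np.nanmean(X[ro])
        if rmean < lmean:
            lo, ro = ro, lo
        return lo + ro

    root = n + len(tree.merges) - 1
    return collect(root)


def to_scipy_linkage(tree: ClusterTree) -> np.ndarray:
    """Convert to a scipy-style linkage matrix (for plotting/interop)."""
    n = tree.n_leaves
    sizes = {i: 1 for i in range(n)}
    Z = np.zeros((n - 1, 4))
    for j, (left, right, d) in enumerate(tree.merges):
        size = sizes[left] + sizes[right]
        sizes[n + j] = size
        Z[j] = [left, right, d, size]
    return Z
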