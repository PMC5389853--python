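"""Per-gene normalization and k-medians clustering of relative binding.

Each transcript's (exo, exo-S1) abundances are reduced to fractions of
their sum, so clustering sees relative route preference rather than
expression level. k-medians follows the Cluster3.0 convention: Lloyd
iterations with Euclidean assignment and component-wise median updates,
best of several seeded restarts by objective. Cluster labels are
renumbered so the mean of the last column (the exo-S1 fraction)
ascends: cluster 1 is the most S1-dependent (direct access), cluster k
the least (threaded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ClusterResult:
    labels: np.ndarray  # 1-based cluster label per row
    medians: np.ndarray  # k x p
    objective: float  # sum of Euclidean distances to assigned medians
    k: int
    seed: int
    restarts: int
    normalization: str = "row_sum"


def normalize_rows(matrix: pd.DataFrame, variant: str = "row_sum"):
    """Row-normalize a two-column (exo, exo-S1) matrix.

    ``row_sum`` divides each row by its sum (fractions summing to 1, the
    relative-binding reading); ``unit_magnitude`` divides by the row's
    Euclidean norm (the Cluster3.0-style alternative). All-zero rows are
    dropped and reported.

    Returns ``(normalized DataFrame, list of dropped gene ids)``.
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("negative values in binding matrix")
    sums = matrix.sum(axis=1)
    dropped = matrix.index[sums == 0].tolist()
    kept = matrix.loc[sums > 0]
    if variant == "row_sum":
        normed = kept.div(kept.sum(axis=1), axis=0)
    elif variant == "unit_magnitude":
        norms = np.sqrt((kept ** 2).sum(axis=1))
        normed = kept.div(norms, axis=0)
    else:
        raise ValueError(f"unknown normalization {variant!r}")
    return normed, dropped


def _assign(X: np.ndarray, medians: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(X[:, None, :] - medians[None, :, :], axis=2)
    return d.argmin(axis=1)


def _objective(X: np.ndarray, medians: np.ndarray,
               labels: np.ndarray) -> float:
    return float(np.linalg.norm(X - medians[labels], axis=1).sum())


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int = 300):
    n = len(X)
    medians = X[rng.choice(n, size=k, replace=False)].astype(float)
    labels = _assign(X, medians)
    prev_obj = np.inf
    for _ in range(max_iter):
        for j in range(k):
            members = X[labels == j]
            if len(members):
                medians[j] = np.median(members, axis=0)
            else:  # reseed an empty cluster from the farthest point
                far = np.linalg.norm(X - medians[labels], axis=1).argmax()
                medians[j] = X[far]
        labels = _assign(X, medians)
        obj = _objective(X, medians, labels)
        if obj >= prev_obj - 1e-12:
            break
        prev_obj = obj
    return labels, medians, _objective(X, medians, labels)


def kmedians(matrix, k: int = 4, seed: int = 0,
             restarts: int = 50) -> ClusterResult:
    """k-medians clustering, best of ``restarts`` seeded initializations.

    Deterministic given ``seed``; invariant to row permutation of the
    input (the returned labels follow the input row order but the
    medians and objective do not depend on it).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if k > len(X):
        raise ValueError(f"k={k} exceeds {len(X)} rows")
    # permutation invariance: restart seeds index rows through a
    # canonical (lexicographic) ordering of the data
    canon = np.lexsort(X.T[::-1])
    Xc = X[canon]
    best = None
    for r in range(restarts):
        rng = np.random.default_rng((seed, r))
        labels_c, medians, obj = _lloyd(Xc, k, rng)
        if best is None or obj < best[2] - 1e-12:
            best = (labels_c, medians, obj)
    labels_c, medians, obj = best
    labels = np.empty(len(X), dtype=int)
    labels[canon] = labels_c

    # renumber clusters by ascending mean of the last column
    order = np.argsort([
        X[labels == j, -1].mean() if (labels == j).any() else np.inf
        for j in range(k)
    ], kind="stable")
    remap = {int(old): new + 1 for new, old in enumerate(order)}
    labels = np.array([remap[int(l)] for l in labels])
    medians = medians[order]
    return ClusterResult(labels=labels, medians=medians, objective=obj,
                         k=k, seed=seed, restarts=restarts)


def cluster_relative_binding(counts: pd.DataFrame, labels: pd.Series,
                             reference: str = "Rrp44-exo") -> pd.DataFrame:
    """Per-cluster protein binding relative to the reference construct.

    ``counts`` holds replicate-averaged values (genes x proteins);
    ``labels`` maps each gene to its cluster. Each protein's per-cluster
    sum is divided by that cluster's reference-construct sum; clusters
    with a zero reference sum yield missing values.
    """
    if reference not in counts.columns:
        raise ValueError(f"reference column {reference!r} absent")
    if not set(counts.index) <= set(labels.index):
        raise ValueError("labels do not cover all genes in counts")
    sums = counts.groupby(labels.loc[counts.index]).sum()
    ref = sums[reference]
    rel = sums.div(ref, axis=0)
    rel[ref == 0] = np.nan
    return rel
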