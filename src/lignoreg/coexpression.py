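"""Co-expression clustering of log2 expression profiles.

Profiles are grouped by a k-medians variant of Lloyd's algorithm under
Pearson correlation distance, d = 1 − r, the combination used by the TM4
MultiExperiment Viewer's k-means/medians tool for expression heat maps.
Cluster centers are the element-wise medians of their members.

Because the element-wise median is not the exact minimizer of summed
Pearson distance, a naive update/reassign loop can cycle or let the
objective creep upward.  The loop here therefore treats the within-cluster
distance sum — evaluated with median centers, a pure function of the
partition — as the objective, and accepts a nearest-center reassignment
sweep only when it strictly lowers that objective.  This makes the descent
monotone, guarantees termination, and makes "converged" mean that no
nearest-center sweep improves the partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionProfile",
    "ClusterAssignment",
    "pearson_distance",
    "kmedians_cluster",
    "consensus_over_restarts",
]


@dataclass
class ExpressionProfile:
    gene_id: str
    values: np.ndarray  # log2 expression over an ordered condition list


@dataclass
class ClusterAssignment:
    labels: dict[str, int]  # gene_id -> 1..k
    centers: pd.DataFrame  # k rows (cluster label) x conditions, element-wise medians
    n_iterations: int
    converged: bool
    objective: float  # sum of Pearson distances to own-cluster median center
    excluded: tuple[str, ...] = ()  # zero-variance profiles left unclustered
    objective_trace: tuple[float, ...] = ()  # objective after each accepted sweep


def pearson_distance(a, b) -> float:
    """Pearson correlation distance d = 1 − r, in [0, 2].

    Both vectors must have length ≥ 3 and nonzero variance (callers
    pre-filter flat profiles; Pearson is undefined for them).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("profiles differ in length")
    if len(a) < 3:
        raise ValueError("profiles must have length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance profile: Pearson distance undefined")
    return float(1.0 - stats.pearsonr(a, b)[0])


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    """Row-standardize; flat rows become zero rows (treated as r = 0)."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    out = np.zeros_like(x, dtype=float)
    np.divide(x - mu, sd, out=out, where=sd > 0)
    return out


def _distance_matrix(x: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Pairwise 1 − r between profile rows and center rows."""
    m = x.shape[1]
    return 1.0 - (_zscore_rows(x) @ _zscore_rows(centers).T) / m


def _partition_objective(x: np.ndarray, labels: np.ndarray, k: int) -> tuple[float, np.ndarray]:
    centers = np.stack([np.median(x[labels == j], axis=0) for j in range(k)])
    d = _distance_matrix(x, centers)
    return float(d[np.arange(len(labels)), labels].sum()), centers


def _repair_empty(labels: np.ndarray, k: int, d_to_own: np.ndarray) -> np.ndarray:
    """Give each empty cluster the profile farthest from its assigned center
    (ties -> lowest profile index), never emptying the donor."""
    labels = labels.copy()
    for j in range(k):
        if np.any(labels == j):
            continue
        counts = np.bincount(labels, minlength=k)
        movable = counts[labels] > 1
        cand = np.where(movable)[0]
        far = cand[np.argmax(d_to_own[cand])]
        labels[far] = j
    return labels


def kmedians_cluster(
    profiles: pd.DataFrame,
    k: int = 10,
    max_iter: int = 50,
    seed: int = 0,
    init_labels: np.ndarray | None = None,
) -> ClusterAssignment:
    """Cluster expression profiles (rows = genes) into k groups.

    Initialization is a seeded random partition (or ``init_labels``,
    0-based).  Each sweep recomputes median centers, reassigns every profile
    to its nearest center (tie -> lowest cluster index), repairs empty
    clusters, and accepts the sweep only if the partition objective strictly
    decreases.  Zero-variance profiles are excluded with a warning.
    """
    flat = profiles.index[(profiles.max(axis=1) - profiles.min(axis=1)) == 0]
    if len(flat):
        warnings.warn(
            f"excluding {len(flat)} zero-variance profile(s) from clustering: "
            f"{list(flat[:5])}..."
        )
        profiles = profiles.drop(index=flat)
    n = len(profiles)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} must be between 1 and the number of profiles ({n})")
    x = profiles.to_numpy(dtype=float)

    if init_labels is not None:
        labels = np.asarray(init_labels, dtype=int)
        if sorted(set(labels)) != list(range(k)):
            raise ValueError("init_labels must use every cluster 0..k-1")
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        labels = np.empty(n, dtype=int)
        labels[perm[:k]] = np.arange(k)  # guarantee no empty cluster
        labels[perm[k:]] = rng.integers(0, k, size=n - k)

    obj, centers = _partition_objective(x, labels, k)
    trace = [obj]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d = _distance_matrix(x, centers)
        new_labels = np.argmin(d, axis=1)  # ties -> lowest index
        new_labels = _repair_empty(new_labels, k, d[np.arange(n), new_labels])
        if np.array_equal(new_labels, labels):
            converged = True
            break
        new_obj, new_centers = _partition_objective(x, new_labels, k)
        if new_obj < obj - 1e-12:
            labels, obj, centers = new_labels, new_obj, new_centers
            trace.append(obj)
        else:
            converged = True
            break

    return ClusterAssignment(
        labels={g: int(l) + 1 for g, l in zip(profiles.index, labels)},
        centers=pd.DataFrame(
            centers, index=pd.RangeIndex(1, k + 1, name="cluster"),
            columns=profiles.columns,
        ),
        n_iterations=it,
        converged=converged,
        objective=obj,
        excluded=tuple(flat),
        objective_trace=tuple(trace),
    )


def consensus_over_restarts(
    profiles: pd.DataFrame,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 50,
) -> tuple[ClusterAssignment, float]:
    """Best-of-n restarts plus a stability score.

    Returns the restart with minimal objective and the mean pairwise
    adjusted Rand index across all restarts (1 = every restart found the
    same partition).
    """
    from sklearn.metrics import adjusted_rand_score

    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    runs = [
        kmedians_cluster(profiles, k=k, max_iter=max_iter, seed=seed + i)
        for i in range(n_restarts)
    ]
    best = min(runs, key=lambda r: r.objective)
    if n_restarts == 1:
        return best, 1.0
    genes = sorted(runs[0].labels)
    aris = [
        adjusted_rand_score(
            [a.labels[g] for g in genes], [b.labels[g] for g in genes]
        )
        for i, a in enumerate(runs)
        for b in runs[i + 1 :]
    ]
    return best, float(np.mean(aris))
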