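"""Exploratory structure analysis of a presence/absence matrix.

Species that share derived gene losses sit close together under the
Manhattan metric (for binary rows, the count of genes with differing
states — which also equals their squared Euclidean distance).  Three
complementary views are provided:

* fuzzy clustering of the distance matrix with the Kaufman–Rousseeuw
  (fanny-style) relational criterion, giving per-species membership
  proportions in each of K clusters;
* classical (Torgerson) metric MDS with k-means hard partitioning of the
  reduced coordinates;
* cluster-count diagnostics — within-cluster dispersion per K (for the
  elbow heuristic) and the adjusted Rand index between the partitions at
  successive K (which clusters are stable as K grows).

The fuzzifier m controls how soft memberships are; m → 1 collapses to
hard assignment (and is degenerate for the update), so the default is a
mildly fuzzy m = 1.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .toga_io import PresenceMatrix

__all__ = [
    "DistanceMatrix",
    "FuzzyModel",
    "MdsResult",
    "pairwise_distances",
    "fuzzy_cluster",
    "reduce_and_partition",
    "cluster_diagnostics",
]

METRICS = ("manhattan", "euclidean", "jaccard")


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, nonnegative, zero diagonal

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")


@dataclass
class FuzzyModel:
    K: int
    m: float
    U: pd.DataFrame  # species × K memberships, rows sum to 1
    objective: float
    iterations: int
    objective_trace: list[float] = field(default_factory=list)

    def hard_labels(self) -> dict[str, int]:
        return {s: int(np.argmax(row)) for s, row in zip(self.U.index, self.U.values)}


@dataclass
class MdsResult:
    coordinates: pd.DataFrame  # species × dims
    eigenvalues: np.ndarray  # decreasing, for the retained axes
    dims: int


def pairwise_distances(matrix: PresenceMatrix, metric: str = "manhattan") -> DistanceMatrix:
    """Species × species distances on the binary rows."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    scipy_metric = {"manhattan": "cityblock", "euclidean": "euclidean",
                    "jaccard": "jaccard"}[metric]
    X = matrix.states.astype(float)
    d = squareform(pdist(X, metric=scipy_metric))
    return DistanceMatrix(list(matrix.species), d)


def _relational_objective(U: np.ndarray, D: np.ndarray, m: float) -> float:
    W = U**m
    total = 0.0
    for k in range(U.shape[1]):
        w = W[:, k]
        denom = 2.0 * w.sum()
        if denom > 0:
            total += float(w @ D @ w) / denom
    return total


def fuzzy_cluster(
    D: DistanceMatrix,
    K: int,
    m: float = 1.2,
    tol: float = 1e-9,
    max_iter: int = 300,
    seed: int = 0,
) -> FuzzyModel:
    """Fanny-style fuzzy clustering of a distance matrix.

    Minimises sum_k (sum_ij u_ik^m u_jk^m d_ij) / (2 sum_j u_jk^m) with the
    relational fuzzy c-means alternating update (exact fuzzy c-means in the
    embedded space when d is squared Euclidean, as Manhattan on binary rows
    is).  The iteration stops when the objective improves by less than
    ``tol``, hits ``max_iter``, or would increase (possible for distance
    matrices with no Euclidean embedding), in which case the previous
    memberships are kept.
    """
    n = len(D.labels)
    if not 2 <= K < n:
        raise ValueError(f"K must satisfy 2 <= K < n={n}")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1 (m -> 1 is hard k-means; "
                         "use reduce_and_partition for a crisp partition)")
    rng = np.random.default_rng(seed)
    U = rng.dirichlet(np.ones(K), size=n)
    obj = _relational_objective(U, D.d, m)
    trace = [obj]
    exponent = 1.0 / (m - 1.0)
    for iteration in range(1, max_iter + 1):
        W = U**m
        Unew = np.empty_like(U)
        a = np.empty((n, K))
        for k in range(K):
            w = W[:, k]
            tot = w.sum()
            v = w / tot
            Dv = D.d @ v
            a[:, k] = Dv - 0.5 * float(v @ Dv)
        a = np.maximum(a, 0.0)
        zero_rows = np.isclose(a, 0.0).any(axis=1)
        with np.errstate(divide="ignore"):
            inv = a ** (-exponent)
        Unew = inv / inv.sum(axis=1, keepdims=True)
        for i in np.flatnonzero(zero_rows):
            hits = np.isclose(a[i], 0.0)
            Unew[i] = hits / hits.sum()
        new_obj = _relational_objective(Unew, D.d, m)
        if new_obj > obj + 1e-12:
            break  # non-embeddable input; keep the last descending state
        U = Unew
        improved = obj - new_obj
        obj = new_obj
        trace.append(obj)
        if improved < tol:
            break
    frame = pd.DataFrame(U, index=D.labels,
                         columns=[f"cluster{k}" for k in range(K)])
    return FuzzyModel(K, m, frame, obj, len(trace) - 1, trace)


def classical_mds(D: DistanceMatrix, dims: int) -> MdsResult:
    """Torgerson MDS: double-centre -d²/2, keep the top positive axes."""
    import warnings

    n = len(D.labels)
    if dims < 1:
        raise ValueError("dims must be >= 1")
    if dims > n - 1:
        raise ValueError("dims must be <= n - 1")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D.d**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > max(1e-9, 1e-12 * abs(eigval[0]))
    n_pos = int(positive.sum())
    use = min(dims, n_pos)
    if use < dims:
        warnings.warn(
            f"only {n_pos} positive MDS axes available (requested {dims})",
            stacklevel=2,
        )
    if use == 0:
        coords = np.zeros((n, 1))
        kept = np.zeros(1)
    else:
        coords = eigvec[:, :use] * np.sqrt(eigval[:use])
        kept = eigval[:use]
    frame = pd.DataFrame(coords, index=D.labels,
                         columns=[f"axis{j+1}" for j in range(coords.shape[1])])
    return MdsResult(frame, kept, dims)


def reduce_and_partition(
    D: DistanceMatrix, dims: int = 4, K: int = 4, seed: int = 0
) -> tuple[MdsResult, dict[str, int]]:
    """Classical MDS followed by seeded multi-start k-means hard labels."""
    mds = classical_mds(D, dims)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > len(D.labels):
        raise ValueError("K cannot exceed the number of species")
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    labels = km.fit_predict(mds.coordinates.values)
    return mds, {s: int(l) for s, l in zip(D.labels, labels)}


def cluster_diagnostics(
    D: DistanceMatrix,
    K_range: Sequence[int] = range(2, 11),
    seed: int = 0,
    dims: int | None = None,
) -> pd.DataFrame:
    """Per K: within-cluster sum of squares (elbow curve) and the adjusted
    Rand index between the K and K-1 partitions (partition stability).

    Partitions come from k-means on the classical-MDS embedding (all
    positive axes unless ``dims`` is given)."""
    n = len(D.labels)
    ks = [int(k) for k in K_range]
    if any(not 2 <= k <= n - 1 for k in ks):
        raise ValueError(f"every K must lie in [2, {n-1}]")
    import warnings

    with warnings.catch_warnings():
        # asking for every axis; fewer positive ones is the normal case here
        warnings.filterwarnings("ignore", message=".*positive MDS axes.*")
        mds = classical_mds(D, dims if dims is not None else n - 1)
    X = mds.coordinates.values
    rows = []
    prev_labels = None
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        wss = float(km.inertia_)
        ari = (
            float(adjusted_rand_score(prev_labels, km.labels_))
            if prev_labels is not None
            else np.nan
        )
        rows.append({"K": k, "wss": wss, "ari_with_prev": ari})
        prev_labels = km.labels_
    return pd.DataFrame(rows)
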