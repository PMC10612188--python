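"""Variability-group clustering and internal validation indices.

Patients are partitioned in (HVS, SD) feature space — or (HVS, VIM) in
the sensitivity variant — by K-means, K-medians, or rank tertiles.
Partitions are scored with three internal validation indices
(Calinski-Harabasz, Davies-Bouldin, Silhouette), the number of clusters
is selected over k = 2..9 by combining the Davies-Bouldin and
Silhouette ranks, and a three-cluster solution is ordered into
low/medium/high variability groups by within-cluster mean HVS.

All algorithms here are implemented from first principles and are
cross-checked in the test suite against independent naive oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Scaling",
    "ClusterModel",
    "ValidationScores",
    "standardize",
    "apply_scaling",
    "kmeans_fit",
    "kmedians_fit",
    "quantile_clusters",
    "silhouette_index",
    "davies_bouldin_index",
    "calinski_harabasz_index",
    "validation_scores",
    "select_k",
    "order_clusters",
]

GROUP_NAMES = ("low", "medium", "high")


@dataclass(frozen=True)
class Scaling:
    """Per-column center/spread used to standardize features."""

    columns: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray


def standardize(X, columns: tuple[str, ...] | None = None) -> tuple[np.ndarray, Scaling]:
    """Z-score each column (n-1 SD); returns (Z, scaling).

    Raises on a zero-spread column, naming it.
    """
    if isinstance(X, pd.DataFrame):
        columns = tuple(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("standardize needs a 2-D array with >= 2 rows")
    if columns is None:
        columns = tuple(f"col{i}" for i in range(X.shape[1]))
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(scale == 0)
    if bad.size:
        raise ValueError(f"zero-spread column(s): {[columns[i] for i in bad]}")
    return (X - center) / scale, Scaling(columns, center, scale)


def apply_scaling(X, scaling: Scaling) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X[list(scaling.columns)].to_numpy(dtype=float)
    return (np.asarray(X, dtype=float) - scaling.center) / scaling.scale


@dataclass
class ClusterModel:
    """A fitted partition of patients in standardized feature space."""

    method: str  # kmeans | kmedians | quantile
    k: int
    centroids: np.ndarray  # (k, d) in standardized space
    labels: np.ndarray  # (n,) ints in 0..k-1
    objective: float  # within-cluster SSE (kmeans) or L1 deviation (kmedians)
    seed: int | None = None
    n_init: int = 1
    scaling: Scaling | None = None
    order_map: dict[int, str] | None = None
    objective_trace: np.ndarray | None = None  # per-iteration, best restart

    def group_names(self) -> np.ndarray:
        """Per-patient low/medium/high labels (requires order_map)."""
        if self.order_map is None:
            raise ValueError("order_map not set; call order_clusters first")
        lut = np.empty(self.k, dtype=object)
        for lab, name in self.order_map.items():
            lut[lab] = name
        return lut[self.labels]

    def predict(self, X) -> np.ndarray:
        """Assign new points (raw feature space if scaling stored)."""
        Z = apply_scaling(X, self.scaling) if self.scaling is not None else np.asarray(X, float)
        dist = _distances(Z, self.centroids, self.method)
        return dist.argmin(axis=1)


def _distances(X: np.ndarray, C: np.ndarray, method: str) -> np.ndarray:
    diff = X[:, None, :] - C[None, :, :]
    if method == "kmedians":
        return np.abs(diff).sum(axis=2)
    return (diff**2).sum(axis=2)  # squared Euclidean for kmeans assignment


def _plusplus_init(X: np.ndarray, k: int, rng: np.random.Generator, method: str) -> np.ndarray:
    """k-means++-style seeding (distance weights; L1 for kmedians)."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d = _distances(X, centers[:1], method).ravel()
    for j in range(1, k):
        total = d.sum()
        if total <= 0:
            centers[j] = X[rng.integers(n)]
        else:
            centers[j] = X[rng.choice(n, p=d / total)]
        d = np.minimum(d, _distances(X, centers[j : j + 1], method).ravel())
    return centers


def _lloyd(
    X: np.ndarray, k: int, rng: np.random.Generator, method: str, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    n = X.shape[0]
    C = _plusplus_init(X, k, rng, method)
    labels = np.full(n, -1)
    trace = []
    for _ in range(max_iter):
        dist = _distances(X, C, method)
        new_labels = dist.argmin(axis=1)  # argmin -> lowest label on ties
        # Empty-cluster repair: re-seed at the point farthest from its centroid.
        assigned_d = dist[np.arange(n), new_labels]
        for j in range(k):
            if not np.any(new_labels == j):
                far = int(np.argmax(assigned_d))
                C[j] = X[far]
                new_labels[far] = j
                assigned_d[far] = 0.0
        trace.append(float(dist[np.arange(n), new_labels].sum()))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            pts = X[labels == j]
            C[j] = np.median(pts, axis=0) if method == "kmedians" else pts.mean(axis=0)
    dist = _distances(X, C, method)
    labels = dist.argmin(axis=1)
    obj = float(dist[np.arange(n), labels].sum())
    trace.append(obj)
    return labels, C, obj, np.asarray(trace)


def _fit(X, k, seed, n_init, method, max_iter, scaling=None) -> ClusterModel:
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points n={n}")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=({"kmeans": 11, "kmedians": 13}[method],))
    best = None
    for child in ss.spawn(n_init):
        rng = np.random.default_rng(child)
        labels, C, obj, trace = _lloyd(X, k, rng, method, max_iter)
        if best is None or obj < best[2]:
            best = (labels, C, obj, trace)
    labels, C, obj, trace = best
    return ClusterModel(
        method=method,
        k=k,
        centroids=C,
        labels=labels,
        objective=obj,
        seed=seed,
        n_init=n_init,
        scaling=scaling,
        objective_trace=trace,
    )


def kmeans_fit(X, k: int, seed: int = 0, n_init: int = 20, max_iter: int = 300,
               scaling: Scaling | None = None) -> ClusterModel:
    """Lloyd's K-means with k-means++ seeding and ``n_init`` restarts.

    The stored objective is the within-cluster sum of squared Euclidean
    distances; it is non-increasing across iterations within a run.
    """
    return _fit(X, k, seed, n_init, "kmeans", max_iter, scaling)


def kmedians_fit(X, k: int, seed: int = 0, n_init: int = 20, max_iter: int = 300,
                 scaling: Scaling | None = None) -> ClusterModel:
    """K-medians: L1 assignment, coordinate-wise median update."""
    return _fit(X, k, seed, n_init, "kmedians", max_iter, scaling)


def quantile_clusters(values, n_groups: int = 3) -> np.ndarray:
    """Rank tertiles (or n-tiles): equal-sized groups up to tie spillover.

    Group sizes differ by at most one (larger groups first); tied values
    are never split across a boundary — the whole tie block joins the
    group of its first member in stable sort order.  If that leaves a
    group empty a warning is emitted.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n == 0:
        raise ValueError("quantile_clusters needs at least one value")
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} values, got {n}")
    order = np.argsort(v, kind="stable")
    sizes = [n // n_groups + (1 if i < n % n_groups else 0) for i in range(n_groups)]
    provisional = np.repeat(np.arange(n_groups), sizes)
    sorted_vals = v[order]
    grp_sorted = provisional.copy()
    block_start = 0
    for i in range(1, n + 1):
        if i == n or sorted_vals[i] != sorted_vals[block_start]:
            grp_sorted[block_start:i] = provisional[block_start]
            block_start = i
    labels = np.empty(n, dtype=int)
    labels[order] = grp_sorted
    present = np.unique(labels)
    if present.size < n_groups:
        warnings.warn(
            f"ties collapsed quantile groups: only {present.size} of "
            f"{n_groups} groups are non-empty",
            stacklevel=2,
        )
    return labels


def _check_labels(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    _, codes = np.unique(labels, return_inverse=True)
    k = codes.max() + 1
    n = X.shape[0]
    if not 2 <= k <= n - 1:
        raise ValueError(f"indices defined only for 2 <= k <= n-1 (k={k}, n={n})")
    return X, codes, int(k)


def silhouette_index(X, labels, chunk: int = 1024) -> float:
    """Mean silhouette over points, Euclidean distance.

    ``s_i = (b_i - a_i) / max(a_i, b_i)`` with ``a_i`` the mean
    intra-cluster distance (excluding self) and ``b_i`` the smallest
    mean distance to another cluster; points in singleton clusters get
    ``s_i = 0``.  Computed in O(n^2) time but O(chunk * n) memory.
    """
    X, codes, k = _check_labels(X, labels)
    n = X.shape[0]
    counts = np.bincount(codes, minlength=k)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), codes] = 1.0
    sq = (X**2).sum(axis=1)
    s_total = 0.0
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d2 = sq[lo:hi, None] + sq[None, :] - 2.0 * (X[lo:hi] @ X.T)
        D = np.sqrt(np.maximum(d2, 0.0))
        S = D @ onehot  # (chunk, k) summed distances per cluster
        own = codes[lo:hi]
        own_count = counts[own]
        with np.errstate(invalid="ignore", divide="ignore"):
            a = S[np.arange(hi - lo), own] / np.maximum(own_count - 1, 1)
            mean_other = S / counts[None, :]
            mean_other[np.arange(hi - lo), own] = np.inf
            b = mean_other.min(axis=1)
            s = (b - a) / np.maximum(a, b)
        s[own_count == 1] = 0.0
        s_total += float(s.sum())
    return s_total / n


def davies_bouldin_index(X, labels) -> float:
    """Davies-Bouldin: mean over clusters of the worst (s_i+s_j)/d_ij."""
    X, codes, k = _check_labels(X, labels)
    centroids = np.vstack([X[codes == j].mean(axis=0) for j in range(k)])
    s = np.array(
        [np.linalg.norm(X[codes == j] - centroids[j], axis=1).mean() for j in range(k)]
    )
    d = np.sqrt(((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(-1))
    off = ~np.eye(k, dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError("coincident centroids: Davies-Bouldin ratio is undefined")
    with np.errstate(divide="ignore"):
        R = (s[:, None] + s[None, :]) / d
    np.fill_diagonal(R, -np.inf)
    return float(R.max(axis=1).mean())


def calinski_harabasz_index(X, labels) -> float:
    """Calinski-Harabasz: [tr(B)/(k-1)] / [tr(W)/(n-k)]."""
    X, codes, k = _check_labels(X, labels)
    n = X.shape[0]
    overall = X.mean(axis=0)
    tr_w = 0.0
    tr_b = 0.0
    for j in range(k):
        pts = X[codes == j]
        c = pts.mean(axis=0)
        tr_w += float(((pts - c) ** 2).sum())
        tr_b += pts.shape[0] * float(((c - overall) ** 2).sum())
    if tr_w == 0:
        raise ValueError("zero within-cluster dispersion (duplicate points)")
    return (tr_b / (k - 1)) / (tr_w / (n - k))


@dataclass(frozen=True)
class ValidationScores:
    k: int
    calinski_harabasz: float
    davies_bouldin: float
    silhouette: float


def validation_scores(X, labels, silhouette_sample: int | None = None,
                      seed: int = 0) -> ValidationScores:
    """All three indices for one partition.

    ``silhouette_sample`` caps the number of points entering the
    silhouette (deterministic subsample; the other two indices are
    always exact).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if silhouette_sample is not None and silhouette_sample < X.shape[0]:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(97,)))
        idx = rng.choice(X.shape[0], size=silhouette_sample, replace=False)
        idx.sort()
        sil = silhouette_index(X[idx], labels[idx])
    else:
        sil = silhouette_index(X, labels)
    _, codes, k = _check_labels(X, labels)
    return ValidationScores(
        k=k,
        calinski_harabasz=calinski_harabasz_index(X, labels),
        davies_bouldin=davies_bouldin_index(X, labels),
        silhouette=sil,
    )


def select_k(
    X,
    k_range=range(2, 10),
    method: str = "kmeans",
    seed: int = 0,
    n_init: int = 20,
    silhouette_sample: int | None = None,
) -> tuple[pd.DataFrame, int]:
    """Score k over ``k_range`` and pick the best.

    The chosen k maximizes the mean rank of (Silhouette, descending
    Davies-Bouldin); Calinski-Harabasz is reported in the table but not
    used in the combination.  Ties go to the smaller k.
    """
    fitter = {"kmeans": kmeans_fit, "kmedians": kmedians_fit}[method]
    rows = []
    for k in k_range:
        model = fitter(X, k, seed=seed, n_init=n_init)
        vs = validation_scores(X, model.labels, silhouette_sample=silhouette_sample, seed=seed)
        rows.append(
            {
                "method": method,
                "k": k,
                "calinski_harabasz": vs.calinski_harabasz,
                "davies_bouldin": vs.davies_bouldin,
                "silhouette": vs.silhouette,
            }
        )
    table = pd.DataFrame(rows)
    rank_sil = table["silhouette"].rank(method="average")
    rank_db = (-table["davies_bouldin"]).rank(method="average")
    combined = (rank_sil + rank_db).to_numpy()
    chosen = int(table["k"].iloc[int(np.argmax(combined))])  # argmax -> first (smallest k)
    return table, chosen


def order_clusters(model: ClusterModel, hvs_values) -> dict[int, str]:
    """Map three cluster labels to low/medium/high by mean HVS.

    ``hvs_values`` is the per-patient HVS aligned with ``model.labels``.
    Stores and returns the mapping.
    """
    if model.k != 3:
        raise ValueError(f"low/medium/high ordering requires k=3, got k={model.k}")
    hvs_values = np.asarray(hvs_values, dtype=float)
    if hvs_values.size != model.labels.size:
        raise ValueError("hvs_values must align with model.labels")
    means = [hvs_values[model.labels == j].mean() for j in range(3)]
    order = np.argsort(means, kind="stable")
    mapping = {int(lab): GROUP_NAMES[rank] for rank, lab in enumerate(order)}
    model.order_map = mapping
    return mapping
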