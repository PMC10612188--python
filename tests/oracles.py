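"""Independent naive oracles used to cross-check the optimized paths.

Everything here is written as plain loops over definitions, on purpose:
these implementations must stay independent of the package internals.
"""

import itertools
import math

import numpy as np


def hvs_loop(values, denominator="intervals"):
    n_changes = 0
    for a, b in zip(values[:-1], values[1:]):
        if abs(b - a) > 0.5:
            n_changes += 1
    denom = len(values) - 1 if denominator == "intervals" else len(values)
    return 100.0 * n_changes / denom


def sd_loop(values):
    m = sum(values) / len(values)
    return math.sqrt(sum((v - m) ** 2 for v in values) / (len(values) - 1))


def mean_loop(values):
    return sum(values) / len(values)


def silhouette_loop(X, labels):
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n = len(X)
    uniq = sorted(set(labels.tolist()))
    scores = []
    for i in range(n):
        own = labels[i]
        same = [j for j in range(n) if labels[j] == own and j != i]
        if not same:
            scores.append(0.0)
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j]) for j in range(n) if labels[j] == c])
            for c in uniq
            if c != own
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def davies_bouldin_loop(X, labels):
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    cents = {c: X[labels == c].mean(axis=0) for c in uniq}
    s = {
        c: np.mean([np.linalg.norm(x - cents[c]) for x in X[labels == c]])
        for c in uniq
    }
    ratios = []
    for ci in uniq:
        worst = max(
            (s[ci] + s[cj]) / np.linalg.norm(cents[ci] - cents[cj])
            for cj in uniq
            if cj != ci
        )
        ratios.append(worst)
    return float(np.mean(ratios))


def calinski_harabasz_loop(X, labels):
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n = len(X)
    uniq = sorted(set(labels.tolist()))
    k = len(uniq)
    overall = X.mean(axis=0)
    tr_w = sum(
        np.sum((X[labels == c] - X[labels == c].mean(axis=0)) ** 2) for c in uniq
    )
    tr_b = sum(
        (labels == c).sum() * np.sum((X[labels == c].mean(axis=0) - overall) ** 2)
        for c in uniq
    )
    return float((tr_b / (k - 1)) / (tr_w / (n - k)))


def kmeans_global_optimum(X, k):
    """Exhaustive minimum within-cluster SSE over all assignments (n small)."""
    X = np.asarray(X, float)
    n = len(X)
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        labels = np.asarray(labels)
        sse = 0.0
        for c in range(k):
            pts = X[labels == c]
            if len(pts):
                sse += float(np.sum((pts - pts.mean(axis=0)) ** 2))
        best = min(best, sse)
    return best


def kmedians_objective_enum(X, k):
    """Exhaustive minimum total L1 deviation from coordinate-wise medians."""
    X = np.asarray(X, float)
    n = len(X)
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        labels = np.asarray(labels)
        obj = 0.0
        for c in range(k):
            pts = X[labels == c]
            if len(pts):
                obj += float(np.sum(np.abs(pts - np.median(pts, axis=0))))
        best = min(best, obj)
    return best


def kmeans_optimum_vectorized(X, k):
    """Exhaustive minimum within-cluster SSE, vectorized over all k^n labelings.

    Same quantity as :func:`kmeans_global_optimum` but feasible up to
    n ~ 12, k = 3.  Enumeration is by base-k digit expansion; empty
    clusters contribute nothing (equivalent to a partition into fewer
    clusters, whose SSE upper-bounds any k-means solution anyway).
    """
    X = np.asarray(X, float)
    n, d = X.shape
    total = k**n
    codes = np.arange(total)
    sq = float(np.sum(X**2))
    best = np.inf
    chunk = 1 << 17
    for lo in range(0, total, chunk):
        c = codes[lo : lo + chunk]
        digits = (c[:, None] // k ** np.arange(n)[None, :]) % k  # (m, n)
        explained = np.zeros(len(c))
        for j in range(k):
            mask = (digits == j).astype(float)
            cnt = mask.sum(axis=1)
            sums = mask @ X  # (m, d)
            nz = cnt > 0
            explained[nz] += (sums[nz] ** 2).sum(axis=1) / cnt[nz]
        best = min(best, float((sq - explained).min()))
    return best


def person_years_rate_ratio(time, event, treated):
    """Crude events-per-person-year ratio, treated vs untreated."""
    time = np.asarray(time, float)
    event = np.asarray(event)
    treated = np.asarray(treated).astype(bool)
    r1 = event[treated].sum() / time[treated].sum()
    r0 = event[~treated].sum() / time[~treated].sum()
    return r1 / r0
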