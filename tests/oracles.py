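"""Independent brute-force oracles.

Everything here is written from the defining formulas with plain loops and
no shared code with the package implementation, so the two can disagree.
Complexity is O(n² log n) or worse; use only at small n.
"""

import numpy as np


def _dist_matrix(X):
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.sqrt(((X[i] - X[j]) ** 2).sum())
    return D


def _knn(D, i, k):
    """Indices of the k nearest neighbors of i, ties broken by index."""
    order = sorted((D[i, j], j) for j in range(D.shape[0]) if j != i)
    return [j for _, j in order[:k]]


def trustworthiness_oracle(X, Z, k):
    D_high = _dist_matrix(X)
    D_low = _dist_matrix(Z)
    n = D_high.shape[0]
    total = 0.0
    for i in range(n):
        order_high = _knn(D_high, i, n - 1)
        rank = {j: pos + 1 for pos, j in enumerate(order_high)}
        for j in _knn(D_low, i, k):
            total += max(0, rank[j] - k)
    return 1.0 - 2.0 / (n * k * (2 * n - 3 * k - 1)) * total


def lcmc_oracle(X, Z, k):
    D_high = _dist_matrix(X)
    D_low = _dist_matrix(Z)
    n = D_high.shape[0]
    overlap = 0
    for i in range(n):
        overlap += len(set(_knn(D_high, i, k)) & set(_knn(D_low, i, k)))
    return overlap / (k * n)


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def _average_ranks(v):
    v = np.asarray(v, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for m in range(i, j + 1):
            ranks[order[m]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    return pearson_oracle(_average_ranks(x), _average_ranks(y))


def bts_oracle(Z, labels, weight_of, k, epsilon=1e-6, metric="euclidean"):
    """weight_of: callable (label_a, label_b) -> weight."""
    Z = np.asarray(Z, float)
    n = Z.shape[0]
    if metric == "euclidean":
        D = _dist_matrix(Z)
    else:  # cosine
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                num = float(Z[i] @ Z[j])
                den = np.linalg.norm(Z[i]) * np.linalg.norm(Z[j])
                D[i, j] = 1.0 - num / den
    num = den = 0.0
    for i in range(n):
        for j in _knn(D, i, k):
            w = weight_of(labels[i], labels[j])
            d = max(D[i, j], epsilon)
            num += w / np.log(d + 1.0)
            den += w
    if den == 0:
        raise ZeroDivisionError("zero BTS denominator")
    return num / den


def silhouette_oracle(Z, labels):
    D = _dist_matrix(Z)
    labels = np.asarray(labels)
    n = len(labels)
    scores = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = np.mean([D[i, j] for j in own])
        b = min(
            np.mean([D[i, j] for j in range(n) if labels[j] == lab])
            for lab in set(labels)
            if lab != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def davies_bouldin_oracle(Z, labels):
    Z = np.asarray(Z, float)
    labels = np.asarray(labels)
    clusters = sorted(set(labels.tolist()))
    cents = {c: Z[labels == c].mean(axis=0) for c in clusters}
    s = {
        c: np.mean([np.linalg.norm(z - cents[c]) for z in Z[labels == c]])
        for c in clusters
    }
    total = 0.0
    for ci in clusters:
        total += max(
            (s[ci] + s[cj]) / np.linalg.norm(cents[ci] - cents[cj])
            for cj in clusters
            if cj != ci
        )
    return total / len(clusters)


def calinski_harabasz_oracle(Z, labels):
    Z = np.asarray(Z, float)
    labels = np.asarray(labels)
    clusters = sorted(set(labels.tolist()))
    n, k = Z.shape[0], len(clusters)
    overall = Z.mean(axis=0)
    tr_b = sum(
        (labels == c).sum() * ((Z[labels == c].mean(axis=0) - overall) ** 2).sum()
        for c in clusters
    )
    tr_w = sum(((Z[labels == c] - Z[labels == c].mean(axis=0)) ** 2).sum() for c in clusters)
    if tr_b == 0:
        return 0.0
    if tr_w == 0:
        return float("inf")
    return tr_b / tr_w * (n - k) / (k - 1)


def soft_metrics_oracle(P):
    P = np.asarray(P, float)
    n, K = P.shape
    ent, sharp, mx = [], [], []
    for row in P:
        H = -sum(p * np.log(p) for p in row if p > 0)
        ent.append(H)
        sharp.append(1.0 - H / np.log(K))
        mx.append(max(row))
    return float(np.mean(ent)), float(np.mean(sharp)), float(np.mean(mx))


def overlap_grid_oracle(kde_p, kde_q, lo, hi, steps=200):
    """∫min(p,q) by dense-grid integration over a 2D box."""
    xs = np.linspace(lo[0], hi[0], steps)
    ys = np.linspace(lo[1], hi[1], steps)
    dx = (xs[1] - xs[0]) * (ys[1] - ys[0])
    XX, YY = np.meshgrid(xs, ys)
    pts = np.vstack([XX.ravel(), YY.ravel()])
    return float(np.minimum(kde_p(pts), kde_q(pts)).sum() * dx)
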