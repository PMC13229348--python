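"""Probabilistic clustering of spine embeddings.

Three methods with one ``SoftPartition`` interface:

* Ward agglomerative clustering (hard, one-hot memberships), merging the
  pair of clusters minimizing D(A,B) = |A||B|/(|A|+|B|)·‖μ_A−μ_B‖²;
* Fuzzy C-Means with fuzzifier m (default 2), alternating centroid /
  membership updates u_ik = 1 / Σ_j (‖z_i−c_k‖/‖z_i−c_j‖)^{2/(m−1)}
  minimizing J_m = ΣΣ u_ik^m ‖z_i − c_k‖²;
* Gaussian mixture fitted by EM, responsibilities
  γ_ik = π_k N(z_i|μ_k,Σ_k) / Σ_j π_j N(z_i|μ_j,Σ_j).

FCM's objective is non-increasing and the GMM log-likelihood non-decreasing
per iteration; both traces are recorded on the returned partition.

Cluster-number selection follows complementary diagnostics: the first peak
of the mean silhouette curve, the Davies-Bouldin minimum, partition balance
(std of cluster sizes), and a CHull elbow -- a scree-ratio test on the
upper convex hull of the (K, within-cluster distortion) curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import logsumexp

from .datatypes import Embedding, SoftPartition


def _coords(low) -> np.ndarray:
    if isinstance(low, Embedding):
        return low.coords
    return np.asarray(low, dtype=float)


@dataclass
class FCMConfig:
    m: float = 2.0  # fuzzifier; m -> 1+ approaches hard assignments
    tol: float = 1e-6
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")


@dataclass
class GMMConfig:
    K: int = 2
    covariance: str = "full"  # or "diagonal"
    tol: float = 1e-7
    max_iter: int = 200
    n_init: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.covariance not in ("full", "diagonal"):
            raise ValueError("covariance must be 'full' or 'diagonal'")


def ward_cluster(low, K: int) -> SoftPartition:
    """Agglomerative Ward clustering; deterministic, one-hot memberships.

    Merge costs under the printed criterion are recorded ascending in
    ``objective_trace`` (scipy's Ward heights h relate to the criterion by
    D = h²/2).
    """
    Z = _coords(low)
    n = Z.shape[0]
    if not 1 <= K <= n:
        raise ValueError(f"K={K} must lie in [1, {n}]")
    link = linkage(Z, method="ward")
    labels = fcluster(link, t=K, criterion="maxclust") - 1
    part = SoftPartition.from_hard_labels(labels, method="ward")
    part.objective_trace = (link[:, 2] ** 2 / 2.0).tolist()
    part.K = part.membership.shape[1]
    return part


def ward_merge_costs(low) -> np.ndarray:
    """All merge costs D(A,B) of the Ward dendrogram, ascending."""
    link = linkage(_coords(low), method="ward")
    return link[:, 2] ** 2 / 2.0


def fcm_memberships(Z: np.ndarray, C: np.ndarray, m: float) -> np.ndarray:
    """One FCM membership update u_ik = 1/Σ_j (d_ik/d_ij)^{2/(m−1)} given
    centroids C; points coinciding with centroids split membership equally
    among the zero-distance clusters."""
    D = np.sqrt(((Z[:, None, :] - C[None, :, :]) ** 2).sum(axis=2))
    expo = 2.0 / (m - 1.0)
    zero = D < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (D[:, :, None] / D[:, None, :]) ** expo
        U = 1.0 / ratio.sum(axis=2)
    rows_zero = zero.any(axis=1)
    if rows_zero.any():
        U[rows_zero] = zero[rows_zero] / zero[rows_zero].sum(axis=1, keepdims=True)
    return U / U.sum(axis=1, keepdims=True)


def fcm_cluster(low, K: int, cfg: FCMConfig | None = None) -> SoftPartition:
    """Fuzzy C-Means from seeded Dirichlet-random memberships.

    Exact coincidence rule: when a point sits on one or more centroids its
    membership is split equally among the zero-distance clusters.
    Non-convergence at ``max_iter`` is reported via ``converged=False``.
    """
    Z = _coords(low)
    n, d = Z.shape
    cfg = cfg or FCMConfig()
    if K < 2:
        raise ValueError("K must be >= 2")
    if n <= K:
        raise ValueError("need N > K")
    rng = np.random.default_rng(cfg.seed)
    U = rng.dirichlet(np.ones(K), size=n)
    trace = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        Um = U**cfg.m
        C = (Um.T @ Z) / Um.sum(axis=0)[:, None]
        D2 = ((Z[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        U_new = fcm_memberships(Z, C, cfg.m)
        trace.append(float(((U_new**cfg.m) * D2).sum()))
        delta = np.max(np.abs(U_new - U))
        U = U_new
        if delta < cfg.tol:
            converged = True
            break
    return SoftPartition(
        membership=U,
        K=K,
        method="fcm",
        converged=converged,
        n_iter=it,
        objective_trace=trace,
        seed=cfg.seed,
    )


def _log_gaussian(Z, mu, cov, diagonal: bool):
    n, d = Z.shape
    if diagonal:
        var = cov if cov.ndim == 1 else np.diag(cov)
        diff = Z - mu
        return -0.5 * (
            d * np.log(2 * np.pi) + np.log(var).sum() + ((diff**2) / var).sum(axis=1)
        )
    chol = np.linalg.cholesky(cov)
    diff = Z - mu
    sol = np.linalg.solve(chol, diff.T)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (d * np.log(2 * np.pi) + logdet + (sol**2).sum(axis=0))


def gmm_cluster(low, cfg: GMMConfig) -> SoftPartition:
    """Gaussian mixture by EM; best of ``n_init`` seeded starts.

    Initialization samples K distinct points as means and takes one hard
    assignment step; covariances are regularized by 1e-6·I. Inits whose
    covariances stay singular are discarded; if all fail an error is raised.
    The per-iteration log-likelihood trace (non-decreasing) is recorded.
    """
    Z = _coords(low)
    n, d = Z.shape
    K = cfg.K
    if n <= K * (d + 1):
        raise ValueError(f"need N > K(d+1) = {K * (d + 1)}")
    rng = np.random.default_rng(cfg.seed)
    reg = 1e-6 * np.eye(d)
    best = None
    failures = []
    for _init in range(cfg.n_init):
        try:
            means = Z[rng.choice(n, size=K, replace=False)].copy()
            assign = np.argmin(((Z[:, None, :] - means[None]) ** 2).sum(axis=2), axis=1)
            pi = np.maximum(np.bincount(assign, minlength=K), 1).astype(float)
            pi /= pi.sum()
            covs = []
            for k in range(K):
                pts = Z[assign == k]
                covs.append(
                    (np.cov(pts.T) if pts.shape[0] > d else np.cov(Z.T)) + reg
                )
            covs = np.array([np.atleast_2d(c) for c in covs])
            trace = []
            gamma = None
            converged = False
            for _it in range(1, cfg.max_iter + 1):
                logp = np.stack(
                    [
                        np.log(pi[k]) + _log_gaussian(Z, means[k], covs[k], cfg.covariance == "diagonal")
                        for k in range(K)
                    ],
                    axis=1,
                )
                norm = logsumexp(logp, axis=1)
                ll = float(norm.sum())
                gamma = np.exp(logp - norm[:, None])
                trace.append(ll)
                if len(trace) > 1 and abs(trace[-1] - trace[-2]) < cfg.tol * abs(trace[-2] or 1.0):
                    converged = True
                    break
                Nk = gamma.sum(axis=0) + 1e-12
                pi = Nk / n
                means = (gamma.T @ Z) / Nk[:, None]
                new_covs = []
                for k in range(K):
                    diff = Z - means[k]
                    cov = (gamma[:, k][:, None] * diff).T @ diff / Nk[k] + reg
                    if cfg.covariance == "diagonal":
                        cov = np.diag(np.diag(cov))
                    np.linalg.cholesky(cov)  # raises if singular despite reg
                    new_covs.append(cov)
                covs = np.array(new_covs)
            cand = dict(
                gamma=gamma, ll=trace[-1], trace=trace, converged=converged
            )
            if best is None or cand["ll"] > best["ll"]:
                best = cand
        except np.linalg.LinAlgError as exc:
            failures.append(str(exc))
            continue
    if best is None:
        raise RuntimeError(f"all {cfg.n_init} GMM initializations failed: {failures}")
    return SoftPartition(
        membership=best["gamma"] / best["gamma"].sum(axis=1, keepdims=True),
        K=K,
        method="gmm",
        converged=best["converged"],
        n_iter=len(best["trace"]),
        objective_trace=best["trace"],
        seed=cfg.seed,
    )


def cluster(low, method: str, K: int, seed: int = 0) -> SoftPartition:
    """Dispatch to one of the three clustering methods."""
    if method == "ward":
        return ward_cluster(low, K)
    if method == "fcm":
        return fcm_cluster(low, K, FCMConfig(seed=seed))
    if method == "gmm":
        return gmm_cluster(low, GMMConfig(K=K, seed=seed))
    raise ValueError(f"unknown clustering method {method!r}")


# ---------------------------------------------------------------------------
# validity metrics


def hard_validity(low, hard_labels) -> tuple:
    """(silhouette, Davies-Bouldin, Calinski-Harabasz) on Euclidean distances.

    Computed from the defining formulas on explicitly differenced distances
    (no dot-product shortcuts), so values agree with naive implementations
    to full floating-point precision. Singleton clusters contribute
    silhouette 0 for their lone member.
    """
    from scipy.spatial.distance import pdist, squareform

    Z = _coords(low)
    labels = np.asarray(hard_labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 clusters")
    if (counts == 0).any():
        raise ValueError("empty cluster")
    if len(uniq) >= Z.shape[0]:
        raise ValueError("every point is its own cluster: silhouette undefined")

    D = squareform(pdist(Z))
    n = Z.shape[0]
    masks = {u: labels == u for u in uniq}
    sil_vals = np.zeros(n)
    for i in range(n):
        own = masks[labels[i]].copy()
        own[i] = False
        if not own.any():
            continue  # singleton: silhouette 0 by convention
        a = D[i, own].mean()
        b = min(D[i, masks[u]].mean() for u in uniq if u != labels[i])
        sil_vals[i] = (b - a) / max(a, b)
    sil = float(sil_vals.mean())

    cents = {u: Z[masks[u]].mean(axis=0) for u in uniq}
    spread = {
        u: float(np.mean(np.linalg.norm(Z[masks[u]] - cents[u], axis=1))) for u in uniq
    }
    db = float(
        np.mean(
            [
                max(
                    (spread[u] + spread[v]) / np.linalg.norm(cents[u] - cents[v])
                    for v in uniq
                    if v != u
                )
                for u in uniq
            ]
        )
    )

    # Calinski-Harabasz with the 0/0 -> 0 convention for coincident data
    overall = Z.mean(axis=0)
    tr_b = sum(
        c * np.sum((Z[labels == u].mean(axis=0) - overall) ** 2)
        for u, c in zip(uniq, counts)
    )
    tr_w = sum(
        np.sum((Z[labels == u] - Z[labels == u].mean(axis=0)) ** 2) for u in uniq
    )
    n, k = Z.shape[0], len(uniq)
    if tr_b == 0:
        ch = 0.0
    elif tr_w == 0:
        ch = float("inf")
    else:
        ch = float(tr_b / tr_w * (n - k) / (k - 1))
    return sil, db, ch


def soft_validity(partition: SoftPartition) -> tuple:
    """(avg entropy, avg sharpness, avg max probability) of memberships.

    Natural log with the 0·log 0 ≡ 0 convention; sharpness is 1 − H_i/log K
    averaged over samples.
    """
    P = partition.membership
    K = partition.K
    if K < 2:
        raise ValueError("sharpness undefined for K=1")
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(P > 0, np.log(P), 0.0)
    H = -(P * logp).sum(axis=1)
    avg_entropy = float(H.mean())
    avg_sharpness = float((1.0 - H / np.log(K)).mean())
    avg_max_prob = float(P.max(axis=1).mean())
    return avg_entropy, avg_sharpness, avg_max_prob


# ---------------------------------------------------------------------------
# cluster-number selection


@dataclass
class KSelectionDiagnostics:
    K_grid: list
    silhouette_by_K: dict
    db_by_K: dict
    size_std_by_K: dict
    distortion_by_K: dict
    chull_elbow_K: int
    first_peak_K: int
    db_best_K: int
    chosen_K: int
    rationale: str = ""
    method: str = "fcm"
    supported_K: list = field(default_factory=list)


def _distortion(Z: np.ndarray, labels: np.ndarray) -> float:
    tot = 0.0
    for u in np.unique(labels):
        pts = Z[labels == u]
        tot += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return tot


def chull_elbow(K_values, distortions) -> int:
    """Scree-ratio elbow on the upper convex hull of (K, −distortion).

    The hull keeps only solutions not dominated by a linear combination of
    simpler and more complex ones; the elbow maximizes the ratio of the
    slope into a point over the slope out of it.
    """
    K_values = list(K_values)
    fit = [-d for d in distortions]  # higher = better
    if len(K_values) < 3:
        return K_values[int(np.argmax(fit))]
    hull = [0]
    for i in range(1, len(K_values)):  # monotone chain, upper hull
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            cross = (K_values[i2] - K_values[i1]) * (fit[i] - fit[i1]) - (
                fit[i2] - fit[i1]
            ) * (K_values[i] - K_values[i1])
            if cross >= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    if len(hull) < 3:
        return K_values[hull[-1]] if len(hull) == 1 else K_values[hull[0]]
    best_ratio, best_i = -np.inf, hull[1]
    for j in range(1, len(hull) - 1):
        i0, i1, i2 = hull[j - 1], hull[j], hull[j + 1]
        s_in = (fit[i1] - fit[i0]) / (K_values[i1] - K_values[i0])
        s_out = (fit[i2] - fit[i1]) / (K_values[i2] - K_values[i1])
        ratio = s_in / s_out if s_out > 0 else np.inf
        if ratio > best_ratio:
            best_ratio, best_i = ratio, i1
    return K_values[best_i]


def first_silhouette_peak(K_values, sils) -> int:
    """Smallest K whose silhouette exceeds both grid neighbors (one-sided at
    the grid ends)."""
    K_values = list(K_values)
    s = list(sils)
    for i, K in enumerate(K_values):
        left_ok = i == 0 or s[i] > s[i - 1]
        right_ok = i == len(s) - 1 or s[i] > s[i + 1]
        if left_ok and right_ok:
            return K
    return K_values[int(np.argmax(s))]


def k_selection_diagnostics(
    low,
    method: str = "fcm",
    K_grid=range(2, 11),
    seed: int = 0,
) -> KSelectionDiagnostics:
    """Evaluate a K grid and choose a cluster number.

    Decision rule: take the CHull elbow when it lies between the first
    silhouette peak and the Davies-Bouldin optimum (inclusive, order-free);
    otherwise take the median of the three candidates.
    """
    Z = _coords(low)
    K_grid = [int(K) for K in K_grid]
    if not K_grid:
        raise ValueError("empty K grid")
    if any(K < 2 or K > Z.shape[0] - 1 for K in K_grid):
        raise ValueError("K grid must lie within [2, N-1]")
    sil, db, size_std, distortion = {}, {}, {}, {}
    for K in K_grid:
        part = cluster(low, method, K, seed=seed)
        labels = part.hard_labels
        if len(np.unique(labels)) < 2:
            sil[K], db[K] = -1.0, np.inf
        else:
            s, d, _ = hard_validity(Z, labels)
            sil[K], db[K] = s, d
        counts = np.bincount(labels, minlength=part.K)
        size_std[K] = float(np.std(counts))
        distortion[K] = _distortion(Z, labels)
    first_peak = first_silhouette_peak(K_grid, [sil[K] for K in K_grid])
    elbow = chull_elbow(K_grid, [distortion[K] for K in K_grid])
    db_best = min(K_grid, key=lambda K: db[K])
    lo, hi = min(first_peak, db_best), max(first_peak, db_best)
    if lo <= elbow <= hi:
        chosen = elbow
        why = "CHull elbow lies between the silhouette first peak and the D-B optimum"
    else:
        chosen = int(np.median([first_peak, elbow, db_best]))
        why = "median of silhouette first peak, CHull elbow and D-B optimum"
    supported = sorted({first_peak, elbow, db_best, chosen})
    rationale = (
        f"first_peak_K={first_peak}, chull_elbow_K={elbow}, db_best_K={db_best}; "
        f"chosen_K={chosen} ({why})"
    )
    return KSelectionDiagnostics(
        K_grid=K_grid,
        silhouette_by_K=sil,
        db_by_K=db,
        size_std_by_K=size_std,
        distortion_by_K=distortion,
        chull_elbow_K=elbow,
        first_peak_K=first_peak,
        db_best_K=db_best,
        chosen_K=chosen,
        rationale=rationale,
        method=method,
        supported_K=supported,
    )
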