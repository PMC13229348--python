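"""Dimensionality-reduction harness: five methods, one seeded interface.

PCA, ISOMAP and t-SNE come from scikit-learn, UMAP from umap-learn. PCUMAP
-- UMAP augmented with a global-structure objective based on Pearson
correlation of pairwise distances -- is implemented as a post-hoc gradient
refinement of a fitted UMAP embedding: coordinates are moved uphill on a
differentiable Pearson correlation between low- and high-dimensional
condensed distance vectors, with an anchor penalty that keeps each point
near its UMAP position (and hence keeps its neighborhood intact).

High-dimensional distances are always Euclidean on the z-scored feature
table so every method is scored on the same basis. All stochastic methods
take an explicit seed; no global RNG state is touched.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datatypes import Embedding, FeatureTable
from .metrics import structure_scores

METHODS = ("pca", "isomap", "tsne", "umap", "pcumap")
DEFAULT_DIM = 3
DEFAULT_N_NEIGHBORS = 15
DEFAULT_PERPLEXITY = 30.0


def fit_embedding(
    table: FeatureTable,
    method: str,
    dim: int = DEFAULT_DIM,
    params: dict | None = None,
    seed: int = 0,
) -> Embedding:
    """Fit one reduction method on a scaled feature table.

    Neighbor counts / perplexity are clamped to the sample size; the values
    actually used are recorded in ``Embedding.params``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if not 2 <= dim <= 5:
        raise ValueError("dim must lie in [2,5]")
    if not table.scaled:
        raise ValueError("fit_embedding requires a standardized table")
    n = table.n
    if n < dim + 2:
        raise ValueError(f"need at least {dim + 2} samples for dim={dim}, got {n}")
    X = table.values
    params = dict(params or {})

    if method == "pca":
        from sklearn.decomposition import PCA

        model = PCA(n_components=dim, random_state=seed)
        coords = model.fit_transform(X)
        params["explained_variance_ratio"] = model.explained_variance_ratio_.tolist()
    elif method == "isomap":
        from sklearn.manifold import Isomap

        nn = int(params.get("n_neighbors", DEFAULT_N_NEIGHBORS))
        if nn >= n:
            nn = n - 1
        if nn < 2:
            raise ValueError(f"isomap needs >= 3 samples (n_neighbors={nn})")
        params["n_neighbors"] = nn
        coords = Isomap(n_neighbors=nn, n_components=dim).fit_transform(X)
    elif method == "tsne":
        from sklearn.manifold import TSNE

        perp = float(params.get("perplexity", DEFAULT_PERPLEXITY))
        perp = min(perp, max(2.0, (n - 1) / 3.0))
        params["perplexity"] = perp
        coords = TSNE(
            n_components=dim,
            perplexity=perp,
            random_state=seed,
            init="pca",
            method="barnes_hut" if dim <= 3 else "exact",
        ).fit_transform(X)
    elif method in ("umap", "pcumap"):
        import umap as umap_

        nn = int(params.get("n_neighbors", DEFAULT_N_NEIGHBORS))
        if nn >= n:
            nn = n - 1
        if nn < 2:
            raise ValueError(f"umap needs >= 3 samples (n_neighbors={nn})")
        params["n_neighbors"] = nn
        model = umap_.UMAP(
            n_components=dim,
            n_neighbors=nn,
            min_dist=float(params.get("min_dist", 0.1)),
            random_state=seed,
        )
        coords = model.fit_transform(X)
        base = Embedding(
            coords=np.asarray(coords, dtype=float),
            method="umap",
            dim=dim,
            params=params,
            seed=seed,
            source_table_id=table.table_id,
        )
        if method == "umap":
            return base
        return refine_pcumap(
            base,
            table,
            lambda_global=float(params.get("lambda_global", 1.0)),
            iters=int(params.get("iters", 150)),
            lr=float(params.get("lr", 0.05)),
            seed=seed,
        )
    return Embedding(
        coords=np.asarray(coords, dtype=float),
        method=method,
        dim=dim,
        params=params,
        seed=seed,
        source_table_id=table.table_id,
    )


def _pearson_distance_objective(Z: np.ndarray, xc: np.ndarray, x_norm: float):
    """Pearson r between fixed centered high-D distances and distances of Z,
    plus its gradient with respect to Z."""
    y = pdist(Z)
    yc = y - y.mean()
    y_norm = np.linalg.norm(yc)
    if y_norm == 0:
        raise FloatingPointError("degenerate embedding: all distances equal")
    r = float(xc @ yc / (x_norm * y_norm))
    # dr/dy_p, then chain through y_p = ||z_i - z_j||
    dr_dy = xc / (x_norm * y_norm) - r * yc / y_norm**2
    with np.errstate(divide="ignore", invalid="ignore"):
        G = squareform(np.where(y > 0, dr_dy / y, 0.0))
    grad = G.sum(axis=1)[:, None] * Z - G @ Z
    return r, grad


def refine_pcumap(
    base: Embedding,
    table: FeatureTable,
    lambda_global: float = 1.0,
    iters: int = 150,
    lr: float = 0.05,
    seed: int = 0,
    anchor: float = 0.5,
) -> Embedding:
    """Gradient refinement of a UMAP embedding toward global fidelity.

    Maximizes J(Z) = λ·pearson(d_high, d_low(Z)) − anchor·mean‖Z−Z₀‖²/s₀
    (s₀ = mean squared spread of Z₀, making the penalty scale-free) by
    ascent with backtracking line search; accepted steps never decrease J.
    The objective trace and the final k-NN overlap with the base embedding
    are recorded in ``params``.
    """
    if base.method != "umap":
        raise ValueError("refine_pcumap expects a umap base embedding")
    if lambda_global < 0:
        raise ValueError("lambda_global must be >= 0")
    Z0 = base.coords.copy()
    Z = Z0.copy()
    params = dict(base.params)
    x = pdist(table.values)
    xc = x - x.mean()
    x_norm = np.linalg.norm(xc)
    if x_norm == 0:
        raise ValueError("constant high-dimensional distances")
    s0 = max(np.mean(np.sum((Z0 - Z0.mean(axis=0)) ** 2, axis=1)), 1e-12)

    def objective(Zc):
        r, grad_r = _pearson_distance_objective(Zc, xc, x_norm)
        disp = np.mean(np.sum((Zc - Z0) ** 2, axis=1)) / s0
        J = lambda_global * r - anchor * disp
        grad = lambda_global * grad_r - anchor * 2.0 * (Zc - Z0) / (Zc.shape[0] * s0)
        return J, grad

    trace = []
    if iters > 0 and lambda_global > 0:
        J, grad = objective(Z)
        trace.append(J)
        step = lr * np.sqrt(s0)
        for _ in range(iters):
            if not np.all(np.isfinite(grad)):
                raise FloatingPointError("non-finite gradient in pcumap refinement")
            gnorm = np.linalg.norm(grad)
            if gnorm < 1e-12:
                break
            accepted = False
            for _bt in range(20):
                Zn = Z + step * grad / gnorm
                Jn, gn = objective(Zn)
                if Jn >= J - 1e-12:
                    accepted = True
                    break
                step *= 0.5
            if not accepted or abs(Jn - J) < 1e-10:
                break
            Z, J, grad = Zn, Jn, gn
            trace.append(J)
            step *= 1.2

    params.update(
        lambda_global=lambda_global,
        iters=iters,
        lr=lr,
        anchor=anchor,
        objective_trace=trace,
        knn_overlap_with_base=_knn_overlap(Z0, Z, k=min(10, Z0.shape[0] - 1)),
    )
    return Embedding(
        coords=Z,
        method="pcumap",
        dim=base.dim,
        params=params,
        seed=seed,
        source_table_id=base.source_table_id,
    )


def _knn_overlap(A: np.ndarray, B: np.ndarray, k: int) -> float:
    from .metrics import lcmc

    if k < 1:
        return 1.0
    return lcmc(A, B, k=k)


def fit_all(
    table: FeatureTable,
    methods=METHODS,
    dim: int = DEFAULT_DIM,
    seed: int = 0,
    params: dict | None = None,
) -> dict:
    """Fit several methods; returns {method: Embedding}. Failures propagate."""
    return {
        m: fit_embedding(table, m, dim=dim, params=(params or {}).get(m), seed=seed)
        for m in methods
    }


def sweep_dimensions(
    table: FeatureTable,
    methods=METHODS,
    dims=(2, 3, 4, 5),
    seed: int = 0,
    k: int = 10,
) -> pd.DataFrame:
    """Structure scores for every (method, dim) combination."""
    dims = list(dims)
    if not dims:
        raise ValueError("dims must be non-empty")
    if any(d not in (2, 3, 4, 5) for d in dims):
        raise ValueError("dims must be a subset of {2,3,4,5}")
    rows = []
    for d in dims:
        for m in methods:
            emb = fit_embedding(table, m, dim=d, seed=seed)
            sc = structure_scores(table, emb, k=min(k, (2 * table.n - 2) // 3 - 1))
            rows.append(
                dict(
                    method=m,
                    dim=d,
                    T=sc.T,
                    LCMC=sc.LCMC,
                    LS=sc.LS,
                    pearson_r=sc.pearson_r,
                    spearman_rho=sc.spearman_rho,
                    GS=sc.GS,
                    SPS=sc.SPS,
                )
            )
    return pd.DataFrame(rows)
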