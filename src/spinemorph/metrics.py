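"""Structure-preservation and biological metrics for embeddings.

Local metrics (trustworthiness T(k), LCMC) score neighborhood fidelity;
global metrics (Pearson r, Spearman ρ on condensed pairwise distances)
score distance-geometry fidelity. They combine into

    LS  = 0.5·T(k) + 0.5·LCMC(k)
    GS  = 0.5·r + 0.5·ρ
    SPS = w_LS·LS + w_GS·GS,      w_LS + w_GS = 1

The Biological Transition Score (BTS) weights nearest-neighbor pairs in the
embedding by how biologically plausible a transition between their expert
labels is (same type 1.0; mushroom↔thin and mushroom↔stubby 0.5;
thin↔stubby 0.0 under the default scheme) and rewards short distances via
1/log(d+1):

    BTS = Σ_i Σ_{j∈NN_i} w(type_i, type_j) / log(d_ij + 1)
          ───────────────────────────────────────────────
               Σ_i Σ_{j∈NN_i} w(type_i, type_j)

with natural logs and a distance floor ``epsilon`` guarding log(1) = 0.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import gaussian_kde, spearmanr

from .datatypes import (
    BTSResult,
    Embedding,
    FeatureTable,
    StructureScores,
    TransitionWeightScheme,
    default_transition_scheme,
)

DEFAULT_K = 10


class UndefinedBTSError(ValueError):
    """All neighbor-pair weights are zero: the BTS denominator vanishes."""


def _as_array(obj) -> np.ndarray:
    if isinstance(obj, FeatureTable):
        return obj.values
    if isinstance(obj, Embedding):
        return obj.coords
    return np.asarray(obj, dtype=float)


def _knn_indices(D: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbors per row of a square distance matrix (self excluded,
    ties broken by index for reproducibility)."""
    n = D.shape[0]
    D = D.copy()
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")
    return order[:, :k]


def trustworthiness(high, low, k: int = DEFAULT_K) -> float:
    """T(k) = 1 − 2/(nk(2n−3k−1)) Σ_i Σ_{j∈N_i^embed} max(0, r(i,j) − k).

    r(i,j) is the rank of j among the original-space neighbors of i
    (1 = nearest); the inner sum runs over embedded-space neighbors, so
    points that are embedding neighbors but originally distant are
    penalized.
    """
    X, Z = _as_array(high), _as_array(low)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if 2 * n - 3 * k - 1 <= 0:
        raise ValueError(f"k={k} violates the normalization bound 2n-3k-1>0 for n={n}")
    Dh = squareform(pdist(X))
    Dl = squareform(pdist(Z))
    nn_embed = _knn_indices(Dl, k)
    order_high = _knn_indices(Dh, n - 1)
    ranks = np.empty((n, n), dtype=int)
    rows = np.repeat(np.arange(n), n - 1)
    ranks[rows, order_high.ravel()] = np.tile(np.arange(1, n), n)
    np.fill_diagonal(ranks, 0)
    r = ranks[np.arange(n)[:, None], nn_embed]
    penalty = np.maximum(0, r - k).sum()
    return float(1.0 - 2.0 / (n * k * (2 * n - 3 * k - 1)) * penalty)


def lcmc(high, low, k: int = DEFAULT_K) -> float:
    """Average fractional k-NN overlap between the two spaces: (1/kn)·Σ|∩|."""
    X, Z = _as_array(high), _as_array(low)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    nn_h = _knn_indices(squareform(pdist(X)), k)
    nn_l = _knn_indices(squareform(pdist(Z)), k)
    overlap = sum(
        len(set(nn_h[i]).intersection(nn_l[i])) for i in range(n)
    )
    return float(overlap / (k * n))


def distance_correlations(high, low, metric: str = "euclidean") -> tuple:
    """(Pearson r, Spearman ρ) between condensed pairwise-distance vectors."""
    X, Z = _as_array(high), _as_array(low)
    if X.shape[0] < 3:
        raise ValueError("need n >= 3")
    dh = pdist(X, metric=metric)
    dl = pdist(Z, metric=metric)
    if dh.std() == 0 or dl.std() == 0:
        raise ValueError("constant distance vector: correlation undefined")
    r = float(np.corrcoef(dh, dl)[0, 1])
    rho = float(spearmanr(dh, dl).statistic)
    return r, rho


def composite_scores(
    T: float,
    LCMC: float,
    pearson_r: float,
    spearman_rho: float,
    w_LS: float = 0.5,
    k: int = DEFAULT_K,
) -> StructureScores:
    """Combine the four component metrics into LS, GS and SPS."""
    if not 0 <= w_LS <= 1:
        raise ValueError("w_LS must lie in [0,1]")
    for name, v, lo, hi in (
        ("T", T, 0, 1),
        ("LCMC", LCMC, 0, 1),
        ("pearson_r", pearson_r, -1, 1),
        ("spearman_rho", spearman_rho, -1, 1),
    ):
        if not lo - 1e-9 <= v <= hi + 1e-9:
            raise ValueError(f"{name}={v} outside [{lo},{hi}]")
    LS = 0.5 * T + 0.5 * LCMC
    GS = 0.5 * pearson_r + 0.5 * spearman_rho
    SPS = w_LS * LS + (1 - w_LS) * GS
    return StructureScores(
        T=T,
        LCMC=LCMC,
        LS=LS,
        pearson_r=pearson_r,
        spearman_rho=spearman_rho,
        GS=GS,
        SPS=SPS,
        w_LS=w_LS,
        w_GS=1 - w_LS,
        k=k,
    )


def structure_scores(high, low, k: int = DEFAULT_K, w_LS: float = 0.5) -> StructureScores:
    """Compute all structure metrics for one embedding against its source."""
    T = trustworthiness(high, low, k=k)
    L = lcmc(high, low, k=k)
    r, rho = distance_correlations(high, low)
    return composite_scores(T, L, r, rho, w_LS=w_LS, k=k)


def bts(
    low,
    labels,
    scheme: TransitionWeightScheme | None = None,
    k: int = DEFAULT_K,
    metric: str = "euclidean",
    epsilon: float = 1e-6,
) -> BTSResult:
    """Biological Transition Score of an embedding given expert labels."""
    Z = _as_array(low)
    labels = [str(x) for x in labels]
    n = Z.shape[0]
    if len(labels) != n:
        raise ValueError("labels length mismatch")
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    scheme = scheme or default_transition_scheme()
    missing = set(labels) - set(scheme.labels)
    if missing:
        raise ValueError(f"labels not in scheme: {sorted(missing)}")
    D = squareform(pdist(Z, metric=metric))
    nn = _knn_indices(D, k)
    lab_idx = np.array([scheme.labels.index(lb) for lb in labels])
    w = scheme.W[lab_idx[:, None], lab_idx[nn]]
    d = D[np.arange(n)[:, None], nn]
    n_floored = int((d < epsilon).sum())
    d = np.maximum(d, epsilon)
    denom = w.sum()
    if denom == 0:
        raise UndefinedBTSError(
            "BTS undefined: every neighbor pair has zero transition weight"
        )
    value = float((w / np.log(d + 1.0)).sum() / denom)
    return BTSResult(
        bts=value,
        distance_metric=metric,
        k=k,
        scheme_name=scheme.name,
        epsilon=epsilon,
        n_floored=n_floored,
    )


def class_overlap(
    low,
    labels,
    n_samples: int = 10_000,
    seed: int = 0,
) -> tuple[dict, float]:
    """Pairwise KDE overlap coefficients ∫min(p,q) and their mean (AO).

    Each class density is a Gaussian KDE with Scott's-rule bandwidth in the
    embedding. The overlap integral is estimated by importance-corrected
    Monte Carlo: draws come from the mixture g = (p+q)/2 and the estimator
    averages min(p,q)/g.
    """
    Z = _as_array(low)
    labels = np.asarray([str(x) for x in labels])
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    d = Z.shape[1]
    kdes = {}
    for c in classes:
        pts = Z[labels == c]
        if pts.shape[0] < d + 2:
            raise ValueError(f"class {c!r} needs >= {d + 2} points for a {d}D KDE")
        kdes[c] = gaussian_kde(pts.T)
    rng = np.random.default_rng(seed)
    overlaps = {}
    for a, b in itertools.combinations(classes, 2):
        p, q = kdes[a], kdes[b]
        m = n_samples // 2
        xs = np.hstack([
            p.resample(m, seed=rng.integers(2**31 - 1)),
            q.resample(n_samples - m, seed=rng.integers(2**31 - 1)),
        ])
        pv, qv = p(xs), q(xs)
        g = 0.5 * (pv + qv)
        ok = g > 0
        ov = float(np.mean(np.minimum(pv[ok], qv[ok]) / g[ok]))
        overlaps[(a, b)] = min(1.0, max(0.0, ov))
    ao = float(np.mean(list(overlaps.values())))
    return overlaps, ao


def sensitivity_suite(
    high,
    low_set: dict,
    labels,
    k_range=range(5, 51, 5),
    w_range=(0.3, 0.4, 0.5, 0.6, 0.7),
    schemes: list | None = None,
    metrics: tuple = ("euclidean", "cosine"),
) -> tuple[pd.DataFrame, dict]:
    """Sweep k, SPS weights and BTS schemes for a set of embeddings.

    Returns a long-format table (method, sweep, parameter, metric, value)
    and per-sweep stability flags: True iff the argmax method is constant
    across the swept grid.
    """
    k_range = list(k_range)
    w_range = list(w_range)
    schemes = schemes or [default_transition_scheme()]
    if not k_range or not w_range or not schemes:
        raise ValueError("sweep ranges must be non-empty")
    rows = []
    for method, low in low_set.items():
        for k in k_range:
            T = trustworthiness(high, low, k=k)
            L = lcmc(high, low, k=k)
            for name, val in (("T", T), ("LCMC", L), ("LS", 0.5 * T + 0.5 * L)):
                rows.append(dict(method=method, sweep="k", parameter=k, metric=name, value=val))
        sc = structure_scores(high, low)
        for w in w_range:
            rows.append(
                dict(
                    method=method,
                    sweep="w_LS",
                    parameter=w,
                    metric="SPS",
                    value=w * sc.LS + (1 - w) * sc.GS,
                )
            )
        for scheme in schemes:
            for metric in metrics:
                res = bts(low, labels, scheme=scheme, metric=metric)
                rows.append(
                    dict(
                        method=method,
                        sweep="bts_scheme",
                        parameter=f"{scheme.name}/{metric}",
                        metric="BTS",
                        value=res.bts,
                    )
                )
    table = pd.DataFrame(rows)
    stability = {}
    for sweep, metric in (("k", "LS"), ("w_LS", "SPS"), ("bts_scheme", "BTS")):
        sub = table[(table.sweep == sweep) & (table.metric == metric)]
        winners = sub.groupby("parameter", sort=False).apply(
            lambda g: g.loc[g.value.idxmax(), "method"], include_groups=False
        )
        stability[sweep] = bool(winners.nunique() == 1)
    return table, stability
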