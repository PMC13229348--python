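"""Post-clustering continuum analyses.

Once an embedding is clustered, these operations quantify how the
partition relates to expert labels (contingency), how clusters touch in
the embedding (nearest-neighbor connectivity), which spines are
transitional (low maximum membership), and which features shift between
confident and ambiguous spines (Cohen's d).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datatypes import Embedding, FeatureTable, SoftPartition


def _coords(low):
    return low.coords if isinstance(low, Embedding) else np.asarray(low, dtype=float)


@dataclass
class ContingencyMatrix:
    counts: pd.DataFrame  # rows = clusters, cols = expert labels

    @property
    def proportions(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    @property
    def row_marginals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def contingency(partition: SoftPartition, labels) -> ContingencyMatrix:
    """Cluster × expert-label count matrix (plus row-normalized proportions)."""
    labels = [str(x) for x in labels]
    if len(labels) != partition.n:
        raise ValueError("labels length mismatch")
    hard = partition.hard_labels
    classes = sorted(set(labels))
    clusters = sorted(set(hard.tolist()))
    counts = pd.DataFrame(0, index=clusters, columns=classes, dtype=int)
    for c, lb in zip(hard, labels):
        counts.loc[c, lb] += 1
    counts.index.name = "cluster"
    return ContingencyMatrix(counts=counts)


@dataclass
class ConnectivityGraph:
    """Cluster-level NN connectivity; ``weights`` sums to 1 over all ordered
    pairs (self pairs included) and is symmetrized by averaging."""

    weights: pd.DataFrame

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        clusters = list(self.weights.index)
        g.add_nodes_from(clusters)
        for i, a in enumerate(clusters):
            for b in clusters[i:]:
                w = self.weights.loc[a, b]
                if a != b:
                    w = w + self.weights.loc[b, a]
                if w > 0:
                    g.add_edge(a, b, weight=float(w))
        return g

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for a in self.weights.index:
            for b in self.weights.columns:
                rows.append(dict(source=a, target=b, weight=self.weights.loc[a, b]))
        return pd.DataFrame(rows)

    @property
    def diagonal_mass(self) -> float:
        return float(np.trace(self.weights.to_numpy()))


def nn_connectivity(low, partition: SoftPartition, k: int = 10) -> ConnectivityGraph:
    """Count Euclidean k-NN pairs by (own cluster, neighbor cluster)."""
    Z = _coords(low)
    n = Z.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < N={n}")
    hard = partition.hard_labels
    D = squareform(pdist(Z))
    np.fill_diagonal(D, np.inf)
    nn = np.argsort(D, axis=1, kind="stable")[:, :k]
    clusters = sorted(set(hard.tolist()))
    idx = {c: i for i, c in enumerate(clusters)}
    W = np.zeros((len(clusters), len(clusters)))
    for i in range(n):
        ci = idx[hard[i]]
        for j in nn[i]:
            W[ci, idx[hard[j]]] += 1.0
    W /= W.sum()
    W = 0.5 * (W + W.T)  # symmetrize directional counts
    return ConnectivityGraph(
        weights=pd.DataFrame(W, index=clusters, columns=clusters)
    )


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Classic Cohen's d with pooled SD ((n1+n2−2) denominator)."""
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        return float("nan")
    s2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    if s2 == 0:
        return 0.0 if np.mean(x) == np.mean(y) else float("inf") * np.sign(np.mean(x) - np.mean(y))
    return float((np.mean(x) - np.mean(y)) / np.sqrt(s2))


@dataclass
class AmbiguityReport:
    threshold: float
    per_spine: pd.DataFrame  # id, max_prob, norm_entropy, flag
    feature_shifts: pd.DataFrame  # feature, cohens_d, rank
    ambiguous_ids: list = field(default_factory=list)
    confident_ids: list = field(default_factory=list)
    d_defined: bool = True


def ambiguity_analysis(
    partition: SoftPartition,
    features: FeatureTable,
    threshold: float = 0.60,
) -> AmbiguityReport:
    """Flag transitional spines and rank the features that separate them.

    A spine is ambiguous when its maximum membership probability is below
    ``threshold``. Cohen's d (confident minus ambiguous) is computed per
    feature; if either side is empty the effect sizes are reported as
    undefined rather than raising.
    """
    if partition.method == "ward":
        raise ValueError("ambiguity analysis requires a soft partition (fcm/gmm)")
    if partition.n != features.n:
        raise ValueError("partition and feature table sizes differ")
    P = partition.membership
    max_prob = P.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(P > 0, np.log(P), 0.0)
    norm_entropy = -(P * logp).sum(axis=1) / np.log(partition.K)
    ambiguous = max_prob < threshold
    per_spine = pd.DataFrame(
        dict(
            id=features.ids,
            max_prob=max_prob,
            norm_entropy=norm_entropy,
            flag=np.where(ambiguous, "ambiguous", "confident"),
        )
    )
    d_defined = bool(ambiguous.any() and (~ambiguous).any())
    rows = []
    for fi, name in enumerate(features.feature_names):
        col = features.values[:, fi]
        d = cohens_d(col[~ambiguous], col[ambiguous]) if d_defined else float("nan")
        rows.append(dict(feature=name, cohens_d=d))
    shifts = pd.DataFrame(rows)
    shifts["abs_d"] = shifts.cohens_d.abs()
    shifts = shifts.sort_values("abs_d", ascending=False, kind="stable").drop(columns="abs_d")
    shifts["rank"] = np.arange(1, len(shifts) + 1)
    return AmbiguityReport(
        threshold=threshold,
        per_spine=per_spine,
        feature_shifts=shifts.reset_index(drop=True),
        ambiguous_ids=[i for i, a in zip(features.ids, ambiguous) if a],
        confident_ids=[i for i, a in zip(features.ids, ambiguous) if not a],
        d_defined=d_defined,
    )


def compare_partitions(low, partitions: dict, reference: str | None = None) -> pd.DataFrame:
    """Hard validity of several partitions on one embedding, side by side.

    ``partitions`` maps name -> SoftPartition (expert labels can be wrapped
    via ``SoftPartition.from_hard_labels``). If ``reference`` names one of
    them, an adjusted Rand index against it is added per row.
    """
    from sklearn.metrics import adjusted_rand_score

    from .clustering import hard_validity

    Z = _coords(low)
    ref_labels = partitions[reference].hard_labels if reference else None
    rows = []
    for name, part in partitions.items():
        sil, db, ch = hard_validity(Z, part.hard_labels)
        row = dict(partition=name, K=part.K, silhouette=sil, db=db, ch=ch)
        if ref_labels is not None:
            row["ari_vs_reference"] = float(
                adjusted_rand_score(ref_labels, part.hard_labels)
            )
        rows.append(row)
    return pd.DataFrame(rows)


def balanced_subset(features: FeatureTable, seed: int = 0) -> FeatureTable:
    """Subsample each class to the smallest class count (seeded, sorted ids)."""
    if features.labels is None:
        raise ValueError("balanced subset requires labels")
    labels = np.asarray(features.labels)
    classes = sorted(set(labels))
    n_min = min((labels == c).sum() for c in classes)
    if n_min < 2:
        raise ValueError("smallest class has < 2 samples")
    rng = np.random.default_rng(seed)
    keep = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        keep.extend(rng.choice(idx, size=n_min, replace=False))
    keep = sorted(keep)
    return FeatureTable(
        values=features.values[keep],
        feature_names=list(features.feature_names),
        ids=[features.ids[i] for i in keep],
        labels=[features.labels[i] for i in keep],
        scaled=False,
        table_id=features.table_id + "-balanced",
        meta={"subset_indices": keep},
    )


def balanced_subset_rerun(
    features: FeatureTable,
    embed_method: str = "pca",
    cluster_method: str = "fcm",
    K: int | None = None,
    dim: int = 3,
    seed: int = 0,
) -> dict:
    """Re-run embedding + clustering on a class-balanced subset.

    Returns contingency matrices and cluster-size standard deviations for
    the full table and the balanced subset, for stability comparison.
    """
    from .clustering import cluster, k_selection_diagnostics
    from .embeddings import fit_embedding

    def run(tab: FeatureTable):
        emb = fit_embedding(tab.standardize(), embed_method, dim=dim, seed=seed)
        if K is None:
            diag = k_selection_diagnostics(emb, method=cluster_method, seed=seed)
            chosen = diag.chosen_K
        else:
            chosen = K
        part = cluster(emb, cluster_method, chosen, seed=seed)
        sizes = np.bincount(part.hard_labels, minlength=part.K)
        return dict(
            embedding=emb,
            partition=part,
            chosen_K=chosen,
            contingency=contingency(part, tab.labels),
            size_std=float(np.std(sizes)),
        )

    sub = balanced_subset(features, seed=seed)
    return {"full": run(features), "balanced": run(sub), "subset_ids": sub.ids}
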