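"""Core containers shared across the pipeline.

Conventions: images are row-major 2D arrays with 0-based pixel indices,
masks are boolean, physical lengths are micrometres via ``pixel_size``
(μm per pixel). Feature tables are pandas-backed; embeddings and membership
matrices are plain ``numpy`` arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

SPINE_LABELS = ("mushroom", "stubby", "thin")


def round_report(x: float, ndigits: int = 3) -> float:
    """Round half away from zero, the convention used for reported scores."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SpineCrop:
    """A single spine: grayscale crop + binary mask (+ optional expert label)."""

    intensity: np.ndarray
    mask: np.ndarray
    pixel_size: float = 1.0
    label: str | None = None
    id: str = ""
    image_params: dict | None = None  # generator ground truth, if synthetic

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.intensity.shape != self.mask.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} != mask shape {self.mask.shape}"
            )
        if self.intensity.ndim != 2:
            raise ValueError("crops must be 2D")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")
        if not self.mask.any():
            raise ValueError("mask has no foreground pixel")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class FeatureTable:
    """N×F numeric feature matrix with names, ids and optional labels."""

    values: np.ndarray
    feature_names: list[str]
    ids: list[str]
    labels: list[str] | None = None
    scaled: bool = False
    scaling_params: dict | None = None  # {"mean": array, "std": array}
    table_id: str = "features"
    meta: dict = field(default_factory=dict)  # e.g. latent_t from the generator

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D")
        n, f = self.values.shape
        if len(self.feature_names) != f:
            raise ValueError("feature_names length mismatch")
        if len(set(self.feature_names)) != f:
            raise ValueError("feature_names must be unique")
        if len(self.ids) != n:
            raise ValueError("ids length mismatch")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length mismatch")
        if np.isnan(self.values).any():
            raise ValueError("feature table contains NaN")
        if self.scaled:
            mu = self.values.mean(axis=0)
            sd = self.values.std(axis=0)
            if np.max(np.abs(mu)) > 1e-8 or np.max(np.abs(sd - 1)) > 1e-8:
                raise ValueError("scaled table violates zero-mean/unit-sd invariant")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def standardize(self) -> "FeatureTable":
        """Z-score each column; constant columns are rejected."""
        if self.scaled:
            return self
        mu = self.values.mean(axis=0)
        sd = self.values.std(axis=0)
        if np.any(sd == 0):
            bad = [self.feature_names[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"cannot standardize constant feature(s): {bad}")
        return FeatureTable(
            values=(self.values - mu) / sd,
            feature_names=list(self.feature_names),
            ids=list(self.ids),
            labels=list(self.labels) if self.labels is not None else None,
            scaled=True,
            scaling_params={"mean": mu, "std": sd},
            table_id=self.table_id,
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "id", self.ids)
        if self.labels is not None:
            df.insert(1, "label", self.labels)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scaled: bool = False) -> "FeatureTable":
        df = df.copy()
        ids = [str(x) for x in df.pop("id")] if "id" in df else [str(i) for i in range(len(df))]
        labels = [str(x) for x in df.pop("label")] if "label" in df else None
        return cls(
            values=df.to_numpy(dtype=float),
            feature_names=[str(c) for c in df.columns],
            ids=ids,
            labels=labels,
            scaled=scaled,
        )

    @classmethod
    def from_csv(cls, path, scaled: bool = False) -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path), scaled=scaled)


@dataclass
class Embedding:
    """Low-dimensional coordinates produced by one reduction method."""

    coords: np.ndarray
    method: str
    dim: int
    params: dict = field(default_factory=dict)
    seed: int = 0
    source_table_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2D")
        if self.coords.shape[1] != self.dim:
            raise ValueError("coords width != dim")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def to_frame(self, ids: list[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords, columns=[f"dim{i + 1}" for i in range(self.dim)]
        )
        df.insert(0, "id", ids if ids is not None else [str(i) for i in range(self.n)])
        df["method"] = self.method
        df["seed"] = self.seed
        return df


@dataclass
class StructureScores:
    """Local/global structure-preservation summary for one embedding.

    LS = w·T + (1−w)·LCMC with equal weights, GS = (r + ρ)/2 and
    SPS = w_LS·LS + w_GS·GS are exact identities maintained by construction.
    """

    T: float
    LCMC: float
    LS: float
    pearson_r: float
    spearman_rho: float
    GS: float
    SPS: float
    w_LS: float
    w_GS: float
    k: int

    def rounded(self, ndigits: int = 3) -> dict:
        return {
            name: round_report(getattr(self, name), ndigits)
            for name in ("T", "LCMC", "LS", "pearson_r", "spearman_rho", "GS", "SPS")
        }


@dataclass
class TransitionWeightScheme:
    """Symmetric label-pair weights in [0,1] encoding plausible transitions."""

    labels: tuple
    W: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.W = np.asarray(self.W, dtype=float)
        L = len(self.labels)
        if self.W.shape != (L, L):
            raise ValueError("weight matrix shape mismatch")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("weight matrix must be symmetric")
        if (self.W < 0).any() or (self.W > 1).any():
            raise ValueError("weights must lie in [0,1]")
        if np.any(np.diag(self.W) < self.W.max(axis=1) - 1e-12):
            raise ValueError("within-type weight must be the row maximum")

    def weight(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.W[ia, ib])


def default_transition_scheme() -> TransitionWeightScheme:
    """Default weights: same-type 1.0; mushroom↔thin / mushroom↔stubby 0.5;
    thin↔stubby 0.0 (rarely observed in remodeling)."""
    W = np.array(
        [
            [1.0, 0.5, 0.5],  # mushroom
            [0.5, 1.0, 0.0],  # stubby
            [0.5, 0.0, 1.0],  # thin
        ]
    )
    return TransitionWeightScheme(labels=SPINE_LABELS, W=W, name="default")


@dataclass
class BTSResult:
    bts: float
    distance_metric: str
    k: int
    scheme_name: str
    epsilon: float
    n_floored: int = 0  # neighbor distances clipped up to epsilon


@dataclass
class SoftPartition:
    """N×K membership matrix with hard labels and convergence info."""

    membership: np.ndarray
    K: int
    method: str
    converged: bool = True
    n_iter: int = 0
    objective_trace: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=float)
        if self.membership.ndim != 2 or self.membership.shape[1] != self.K:
            raise ValueError("membership must be N×K")
        if (self.membership < -1e-12).any() or (self.membership > 1 + 1e-12).any():
            raise ValueError("memberships must lie in [0,1]")
        rows = self.membership.sum(axis=1)
        if np.max(np.abs(rows - 1)) > 1e-9:
            raise ValueError("membership rows must sum to 1")
        if self.method == "ward":
            onehot = np.isclose(self.membership, 0) | np.isclose(self.membership, 1)
            if not onehot.all():
                raise ValueError("ward memberships must be one-hot")

    @property
    def n(self) -> int:
        return self.membership.shape[0]

    @property
    def hard_labels(self) -> np.ndarray:
        return self.membership.argmax(axis=1)

    def to_frame(self, ids: list[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            self.membership, columns=[f"p_{k + 1}" for k in range(self.K)]
        )
        df.insert(0, "id", ids if ids is not None else [str(i) for i in range(self.n)])
        df.insert(1, "hard_label", self.hard_labels)
        df["method"] = self.method
        df["K"] = self.K
        df["seed"] = self.seed
        return df

    @classmethod
    def from_hard_labels(cls, labels, method: str = "ward", seed: int = 0) -> "SoftPartition":
        labels = np.asarray(labels)
        uniq = np.unique(labels)
        member = (labels[:, None] == uniq[None, :]).astype(float)
        return cls(membership=member, K=len(uniq), method=method, seed=seed)


@dataclass
class ArchetypeSpec:
    """One spine archetype: a feature-space Gaussian plus image geometry.

    ``image_params`` holds head_radius (px), neck_length (px), neck_width (px)
    and orientation (rad). Stubby archetypes have near-zero neck_length:
    stubby spines lack a distinct neck.
    """

    label: str
    feature_means: np.ndarray
    feature_cov: np.ndarray
    image_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_cov = np.asarray(self.feature_cov, dtype=float)
        f = self.feature_means.shape[0]
        if self.feature_cov.shape != (f, f):
            raise ValueError("feature_cov shape mismatch")
        if not np.allclose(self.feature_cov, self.feature_cov.T):
            raise ValueError("feature_cov must be symmetric")
        eigs = np.linalg.eigvalsh(self.feature_cov)
        if eigs.min() < -1e-10 * max(1.0, abs(eigs.max())):
            raise ValueError("feature_cov must be positive semi-definite")
        if self.image_params:
            if self.image_params.get("head_radius", 1.0) <= 0:
                raise ValueError("head_radius must be > 0")
            if self.image_params.get("neck_width", 1.0) <= 0:
                raise ValueError("neck_width must be > 0")
            if self.image_params.get("neck_length", 0.0) < 0:
                raise ValueError("neck_length must be >= 0")


@dataclass
class SyntheticSpineSet:
    """Generated crops with ground-truth labels and continuum coordinates."""

    crops: list
    labels: list
    latent_t: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.latent_t = np.asarray(self.latent_t, dtype=float)
        if not (len(self.crops) == len(self.labels) == len(self.latent_t)):
            raise ValueError("crops/labels/latent_t lengths must agree")

    @property
    def n(self) -> int:
        return len(self.crops)
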