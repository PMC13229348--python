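"""Synthetic spine benchmarks with known ground truth.

Real 2PLSM spine datasets come with expert labels but no ground-truth
geometry, so every quantitative contract in this package is exercised on
synthetic data instead: three archetypes (mushroom, stubby, thin) living on
a morphological continuum, the naturally occurring class imbalance
(mushroom > stubby > thin, preset ratio 3:2:1), and a degraded
low-resolution variant emulating a coarser acquisition (block-downsampled
and renoised).

Two generators are provided. ``generate_feature_continuum`` samples feature
vectors directly from per-archetype Gaussians, with a configurable share of
rows interpolated between archetype means (the continuum). ``generate_spine_image_set``
rasterizes parametric spine silhouettes -- ellipse head, rectangle neck,
half-disc shaft junction -- blurs them with a Gaussian PSF and adds noise,
storing the true geometry per crop so morphometric estimates can be audited.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    ArchetypeSpec,
    FeatureTable,
    SpineCrop,
    SyntheticSpineSet,
    SPINE_LABELS,
)

#: class imbalance preset: mushroom : stubby : thin
DEFAULT_IMBALANCE = {"mushroom": 3, "stubby": 2, "thin": 1}

#: archetype pairs between which morphological transitions are common
#: (thin and stubby both remodel via the mushroom form, not into each other)
CONTINUUM_PAIRS = (("mushroom", "stubby"), ("mushroom", "thin"))

_FEATURE_NAMES = [
    "area",
    "perimeter",
    "circularity",
    "eccentricity",
    "solidity",
    "aspect_ratio",
    "neck_length",
    "neck_width",
    "head_diameter",
    "length_width_ratio",
    "intensity_mean",
    "fractal_dimension",
]

# per-archetype feature means (order = _FEATURE_NAMES) and relative sds
_ARCHETYPE_TABLE = {
    "mushroom": dict(
        means=[450, 90, 0.55, 0.60, 0.85, 1.6, 8, 3.0, 24, 1.5, 0.70, 1.15],
        image=dict(head_radius=12.0, neck_length=10.0, neck_width=3.0, orientation=0.0),
    ),
    "stubby": dict(
        means=[260, 60, 0.80, 0.45, 0.95, 1.1, 1, 6.0, 16, 1.0, 0.60, 1.05],
        image=dict(head_radius=8.0, neck_length=0.5, neck_width=6.0, orientation=0.0),
    ),
    "thin": dict(
        means=[140, 70, 0.35, 0.90, 0.70, 3.5, 20, 2.0, 8, 4.0, 0.50, 1.25],
        image=dict(head_radius=4.0, neck_length=20.0, neck_width=2.0, orientation=0.0),
    ),
}

#: per-feature noise sd as a fraction of the cross-archetype mean range
_NOISE_FRACTION = 0.10


def default_archetypes() -> list[ArchetypeSpec]:
    """The three canonical archetypes with well-separated feature means."""
    means = np.array([_ARCHETYPE_TABLE[lb]["means"] for lb in SPINE_LABELS])
    feature_range = means.max(axis=0) - means.min(axis=0)
    sd = _NOISE_FRACTION * feature_range
    cov = np.diag(sd**2)
    return [
        ArchetypeSpec(
            label=lb,
            feature_means=np.array(_ARCHETYPE_TABLE[lb]["means"], dtype=float),
            feature_cov=cov,
            image_params=dict(_ARCHETYPE_TABLE[lb]["image"]),
        )
        for lb in SPINE_LABELS
    ]


def default_feature_names() -> list[str]:
    return list(_FEATURE_NAMES)


def _archetype_map(archetypes: list[ArchetypeSpec]) -> dict:
    return {a.label: a for a in archetypes}


def generate_feature_continuum(
    n_per_class: dict,
    archetypes: list[ArchetypeSpec] | None = None,
    mixing_fraction: float = 0.2,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> FeatureTable:
    """Sample a labeled feature table with continuum structure.

    A ``mixing_fraction`` share of each class's rows is drawn around a point
    on the line segment between its archetype mean and a transition partner
    (partners follow ``CONTINUUM_PAIRS``), at interpolation coordinate
    ``latent_t`` ~ U(0, 0.5) so each row stays closer to its own archetype.
    Remaining rows sit at the archetype mean (latent_t = 0). Per-row Gaussian
    noise uses the archetype covariance. Identical seeds give identical
    tables; the latent coordinates are stored in ``table.meta['latent_t']``.
    """
    if not 0 <= mixing_fraction <= 1:
        raise ValueError("mixing_fraction must lie in [0,1]")
    if archetypes is None:
        archetypes = default_archetypes()
    amap = _archetype_map(archetypes)
    for lb, cnt in n_per_class.items():
        if lb not in amap:
            raise ValueError(f"unknown label {lb!r}: no matching archetype")
        if cnt < 0:
            raise ValueError("counts must be >= 0")
    partners = {}
    for a, b in CONTINUUM_PAIRS:
        partners.setdefault(a, []).append(b)
        partners.setdefault(b, []).append(a)

    rng = np.random.default_rng(seed)
    rows, labels, latent = [], [], []
    order = [lb for lb in (list(SPINE_LABELS) + sorted(set(n_per_class) - set(SPINE_LABELS))) if lb in n_per_class]
    for lb in order:
        arch = amap[lb]
        cands = [amap[p] for p in partners.get(lb, []) if p in amap]
        for _ in range(int(n_per_class[lb])):
            t = 0.0
            mean = arch.feature_means
            if cands and rng.uniform() < mixing_fraction:
                partner = cands[rng.integers(len(cands))]
                t = rng.uniform(0.0, 0.5)
                mean = (1 - t) * arch.feature_means + t * partner.feature_means
            rows.append(rng.multivariate_normal(mean, arch.feature_cov, method="cholesky"))
            labels.append(lb)
            latent.append(t)
    if not rows:
        raise ValueError("no rows requested")
    values = np.asarray(rows)
    names = feature_names or (
        default_feature_names()
        if values.shape[1] == len(_FEATURE_NAMES)
        else [f"f{i}" for i in range(values.shape[1])]
    )
    table = FeatureTable(
        values=values,
        feature_names=names,
        ids=[f"s{i:04d}" for i in range(len(rows))],
        labels=labels,
        table_id=f"continuum-seed{seed}",
        meta={"latent_t": np.asarray(latent), "seed": seed},
    )
    return table


# ---------------------------------------------------------------------------
# image generation


def _rasterize_silhouette(
    shape: tuple,
    head_radius: float,
    neck_length: float,
    neck_width: float,
    orientation: float,
    head_axis_ratio: float = 0.9,
) -> np.ndarray:
    """Boolean silhouette: ellipse head + rectangle neck + half-disc shaft.

    Built in an axis-aligned frame (neck along +y below the head, shaft at
    the bottom) and rotated analytically about the crop centre, so rotation
    introduces no interpolation artefacts.
    """
    h, w = shape
    a = head_radius  # ellipse semi-axis across
    b = head_radius * head_axis_ratio  # ellipse semi-axis along the neck
    shaft_r = max(1.5 * neck_width, 3.0)
    total = 2 * b + neck_length + shaft_r
    if total > min(h, w) - 4 or 2 * a > w - 4:
        raise ValueError(
            f"geometry (extent {total:.1f}px, head {2 * a:.1f}px) exceeds crop bounds {shape}"
        )
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(orientation), np.sin(orientation)
    u = c * dx + s * dy  # across-axis
    v = -s * dx + c * dy  # along-axis, +v toward the shaft
    # centre the structure: head centre at v0, shaft base at v0 + b + neck_length
    v0 = -(neck_length + shaft_r) / 2.0
    head = (u / a) ** 2 + ((v - v0) / b) ** 2 <= 1.0
    neck_top, neck_bot = v0, v0 + b + neck_length
    neck = (np.abs(u) <= neck_width / 2.0) & (v >= neck_top) & (v <= neck_bot)
    shaft = ((u**2 + (v - neck_bot) ** 2) <= shaft_r**2) & (v >= neck_bot)
    return head | neck | shaft


def generate_spine_image_set(
    n: int,
    archetypes: list[ArchetypeSpec] | None = None,
    noise_sd: float = 0.05,
    psf_sigma: float = 1.5,
    seed: int = 0,
    size: int = 128,
    ratios: dict | None = None,
    param_jitter: float = 0.10,
    pixel_size: float = 0.05,
) -> SyntheticSpineSet:
    """Rasterize ``n`` spine crops with ground-truth geometry.

    Class counts follow ``ratios`` (default 3:2:1 imbalance). Head/neck
    parameters are jittered per spine by ±``param_jitter`` (relative) and the
    orientation by ±0.3 rad; the jittered values are stored as the crop's
    ``image_params`` ground truth. Intensity: head 1.0, neck 0.7, shaft 0.8
    before Gaussian PSF blur (``psf_sigma``) and additive Gaussian noise.
    """
    from scipy.ndimage import gaussian_filter

    if n <= 0:
        raise ValueError("n must be > 0")
    if psf_sigma < 0:
        raise ValueError("psf_sigma must be >= 0")
    if archetypes is None:
        archetypes = default_archetypes()
    amap = _archetype_map(archetypes)
    ratios = ratios or {lb: DEFAULT_IMBALANCE.get(lb, 1) for lb in amap}
    labs = [lb for lb in list(SPINE_LABELS) + sorted(set(amap) - set(SPINE_LABELS)) if lb in amap]
    weights = np.array([ratios.get(lb, 1) for lb in labs], dtype=float)
    counts = np.floor(n * weights / weights.sum()).astype(int)
    for i in range(n - counts.sum()):  # distribute the remainder
        counts[i % len(counts)] += 1

    rng = np.random.default_rng(seed)
    crops, labels = [], []
    idx = 0
    for lb, cnt in zip(labs, counts):
        arch = amap[lb]
        ip = arch.image_params
        for _ in range(cnt):
            jit = lambda x: x * (1 + param_jitter * rng.uniform(-1, 1))
            params = dict(
                head_radius=jit(ip["head_radius"]),
                neck_length=max(0.0, jit(ip["neck_length"])),
                neck_width=max(1.0, jit(ip["neck_width"])),
                orientation=ip.get("orientation", 0.0)
                + 3.0 * param_jitter * rng.uniform(-1, 1),
            )
            sil = _rasterize_silhouette((size, size), **params)
            img = np.zeros((size, size), dtype=float)
            # region-wise intensity: re-evaluate head/neck membership
            head_only = _rasterize_silhouette(
                (size, size),
                head_radius=params["head_radius"],
                neck_length=params["neck_length"],
                neck_width=1e-9,
                orientation=params["orientation"],
            )
            img[sil] = 0.75
            img[head_only & sil] = 1.0
            if psf_sigma > 0:
                img = gaussian_filter(img, psf_sigma)
            if noise_sd > 0:
                img = img + rng.normal(0.0, noise_sd, img.shape)
            img = np.clip(img, 0.0, None)
            crops.append(
                SpineCrop(
                    intensity=img,
                    mask=sil,
                    pixel_size=pixel_size,
                    label=lb,
                    id=f"img{idx:04d}",
                    image_params=params,
                )
            )
            labels.append(lb)
            idx += 1
    return SyntheticSpineSet(crops=crops, labels=labels, latent_t=np.zeros(len(crops)), seed=seed)


def _block_reduce_mean(img: np.ndarray, b: int) -> np.ndarray:
    h, w = (img.shape[0] // b) * b, (img.shape[1] // b) * b
    return img[:h, :w].reshape(h // b, b, w // b, b).mean(axis=(1, 3))


def _block_reduce_majority(mask: np.ndarray, b: int) -> np.ndarray:
    h, w = (mask.shape[0] // b) * b, (mask.shape[1] // b) * b
    frac = mask[:h, :w].reshape(h // b, b, w // b, b).mean(axis=(1, 3))
    return frac >= 0.5  # ties count as foreground: preserves thin necks


def degrade_image_set(
    sset: SyntheticSpineSet,
    downsample: int,
    extra_noise_sd: float,
    seed: int = 0,
) -> SyntheticSpineSet:
    """Emulate a coarser acquisition: block-downsample then renoise.

    Intensity blocks are averaged; masks use majority vote with ties kept as
    foreground. Labels, ids, latent coordinates and ground-truth params are
    preserved; pixel_size grows by the factor.
    """
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    if downsample == 1 and extra_noise_sd == 0:
        return SyntheticSpineSet(
            crops=list(sset.crops),
            labels=list(sset.labels),
            latent_t=sset.latent_t.copy(),
            seed=sset.seed,
        )
    rng = np.random.default_rng(seed)
    crops = []
    for crop in sset.crops:
        if downsample > min(crop.intensity.shape):
            raise ValueError("downsample factor larger than image side")
        img = _block_reduce_mean(crop.intensity, downsample)
        mask = _block_reduce_majority(crop.mask, downsample)
        if extra_noise_sd > 0:
            img = np.clip(img + rng.normal(0.0, extra_noise_sd, img.shape), 0.0, None)
        if not mask.any():  # extreme downsampling: keep the densest pixel
            frac = _block_reduce_mean(crop.mask.astype(float), downsample)
            mask = frac >= frac.max()
        crops.append(
            SpineCrop(
                intensity=img,
                mask=mask,
                pixel_size=crop.pixel_size * downsample,
                label=crop.label,
                id=crop.id,
                image_params=dict(crop.image_params or {}),
            )
        )
    return SyntheticSpineSet(
        crops=crops, labels=list(sset.labels), latent_t=sset.latent_t.copy(), seed=sset.seed
    )
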