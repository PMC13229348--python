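"""Disk round-tripping: 16-bit TIFF crop/mask pairs plus a manifest CSV."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import SpineCrop, SyntheticSpineSet

_PARAM_COLS = ("head_radius", "neck_length", "neck_width", "orientation")


def write_spine_set(sset: SyntheticSpineSet, outdir) -> Path:
    """Write crops as 16-bit grayscale TIFFs and return the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for crop, t in zip(sset.crops, sset.latent_t):
        peak = crop.intensity.max()
        scaled = crop.intensity / peak if peak > 0 else crop.intensity
        img16 = (scaled * 65535).round().astype(np.uint16)
        img_path = outdir / f"{crop.id}.tif"
        mask_path = outdir / f"{crop.id}_mask.tif"
        tifffile.imwrite(img_path, img16)
        tifffile.imwrite(mask_path, crop.mask.astype(np.uint16) * 65535)
        row = dict(
            id=crop.id,
            label=crop.label,
            latent_t=float(t),
            image_path=img_path.name,
            mask_path=mask_path.name,
            pixel_size=crop.pixel_size,
        )
        for key in _PARAM_COLS:
            row[key] = (crop.image_params or {}).get(key, np.nan)
        rows.append(row)
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_spine_set(manifest_path) -> SyntheticSpineSet:
    """Load a crop set from a manifest CSV (paths relative to the manifest)."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(str(manifest_path))
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    crops, labels, latent = [], [], []
    for _, row in df.iterrows():
        img = tifffile.imread(base / row["image_path"]).astype(float) / 65535.0
        mask = tifffile.imread(base / row["mask_path"]) > 0
        params = {k: float(row[k]) for k in _PARAM_COLS if k in row and pd.notna(row[k])}
        label = None if pd.isna(row.get("label")) else str(row["label"])
        crops.append(
            SpineCrop(
                intensity=img,
                mask=mask,
                pixel_size=float(row.get("pixel_size", 1.0)),
                label=label,
                id=str(row["id"]),
                image_params=params or None,
            )
        )
        labels.append(label)
        latent.append(float(row.get("latent_t", 0.0)))
    return SyntheticSpineSet(crops=crops, labels=labels, latent_t=np.array(latent), seed=-1)
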