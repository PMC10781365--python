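"""Artifact persistence: images, masks, manifests, arrays, tables.

Every writer here is byte-deterministic given identical inputs, so that a
pipeline run with fixed seeds reproduces its artifacts exactly: PNGs carry
no timestamp chunks, NPZ containers are written with a fixed archive date,
and JSON/CSV are emitted with stable key and row order.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from PIL import Image

from .core import DiscCupAnnotation, Ellipse, FundusSample


# ---------------------------------------------------------------------------
# images and masks


def write_image_png(path, image: np.ndarray) -> None:
    """Write a float [0,1] H x W x 3 image as 8-bit RGB PNG."""
    arr = np.clip(np.round(np.asarray(image) * 255), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path, format="PNG")


def read_image_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"), dtype=float) / 255.0


def write_mask_png(path, mask: np.ndarray) -> None:
    """Binary mask as single-channel 0/255 PNG."""
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8), mode="L").save(path, format="PNG")


def read_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


# ---------------------------------------------------------------------------
# arrays


def save_npz(path, arrays: Mapping[str, np.ndarray]) -> None:
    """NPZ-compatible container with a fixed archive timestamp (reproducible)."""
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for key in sorted(arrays):
            buf = _io.BytesIO()
            np.save(buf, np.asarray(arrays[key]))
            info = zipfile.ZipInfo(f"{key}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, buf.getvalue())


def load_npz(path) -> dict[str, np.ndarray]:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}


# ---------------------------------------------------------------------------
# annotations and manifests


def annotation_to_dict(ann: DiscCupAnnotation) -> dict:
    return {
        "disc": asdict(ann.disc),
        "cup": asdict(ann.cup),
        "laterality": ann.laterality,
    }


def annotation_from_dict(d: dict) -> DiscCupAnnotation:
    return DiscCupAnnotation(
        disc=Ellipse(**d["disc"]), cup=Ellipse(**d["cup"]), laterality=d["laterality"]
    )


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_dataset(
    out_dir,
    samples: list[FundusSample],
    annotations: list[DiscCupAnnotation],
    manifest: pd.DataFrame,
) -> pd.DataFrame:
    """Write images, disc/cup mask PNGs, ellipse annotations and the manifest.

    Returns the manifest augmented with relative artifact paths.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    img_paths, disc_paths, cup_paths = [], [], []
    ann_records = {}
    for sample, ann in zip(samples, annotations):
        shape = sample.image.shape[:2]
        sid = sample.sample_id
        write_image_png(out / "images" / f"{sid}.png", sample.image)
        write_mask_png(out / "masks" / f"{sid}_disc.png", ann.disc_mask(shape))
        write_mask_png(out / "masks" / f"{sid}_cup.png", ann.cup_mask(shape))
        ann_records[sid] = annotation_to_dict(ann)
        img_paths.append(f"images/{sid}.png")
        disc_paths.append(f"masks/{sid}_disc.png")
        cup_paths.append(f"masks/{sid}_cup.png")
    manifest["image_path"] = img_paths
    manifest["disc_mask_path"] = disc_paths
    manifest["cup_mask_path"] = cup_paths
    manifest = manifest[
        ["sample_id", "image_path", "disc_mask_path", "cup_mask_path", "laterality", "label"]
    ]
    manifest.to_csv(out / "manifest.csv", index=False)
    write_json(out / "annotations.json", ann_records)
    return manifest


def read_dataset(out_dir) -> tuple[list[FundusSample], list[DiscCupAnnotation], pd.DataFrame]:
    """Load a dataset written by :func:`write_dataset` (manifest row order)."""
    from .core import LABELS

    out = Path(out_dir)
    manifest = pd.read_csv(out / "manifest.csv")
    ann_records = read_json(out / "annotations.json")
    samples, annotations = [], []
    for row in manifest.itertuples():
        image = read_image_png(out / row.image_path)
        samples.append(
            FundusSample(
                image=image,
                laterality=row.laterality,
                label=LABELS.index(row.label),
                sample_id=row.sample_id,
            )
        )
        annotations.append(annotation_from_dict(ann_records[row.sample_id]))
    return samples, annotations, manifest
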