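"""Synthetic fundus fixtures: image generator, splits, toy training.

The generator emulates the structure that drives disc photography in
glaucoma screening: a textured orange-red background, a brighter elliptical
optic disc, and a brightest cup ellipse inside it.  The discriminative
signal between classes is parametric — glaucomatous samples draw a larger
cup-to-disc ratio (CDR) and, optionally, an eccentric displacement of the
cup toward a chosen sector, emulating sector-localized neuroretinal rim
loss.  Images are disc-centered, as classifiers for this problem typically
receive a disc crop.

All operations are pure functions of their inputs and a seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .core import (
    GLAUCOMA,
    HEALTHY,
    LABELS,
    ConfigurationError,
    DiscCupAnnotation,
    Ellipse,
    FundusSample,
    measured_cdr,
)
from .nn import Hyperparams, ModelAdapter, ToyCNN, fit
from .sectors import OD_TEMPORAL_SIDE, SectorScheme

# intensity palette (R, G, B), chosen to preserve the ordering
# cup > disc > background seen in real disc photographs
_BACKGROUND = np.array([0.72, 0.35, 0.15])
_DISC = np.array([0.93, 0.72, 0.45])
_CUP = np.array([0.98, 0.88, 0.62])
_VESSEL = np.array([0.45, 0.12, 0.10])

# target CDRs are sampled from the configured interval shrunk by this margin
# so that mask-measured CDRs stay inside the interval despite rasterization
_CDR_RASTER_MARGIN = 0.01


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic fundus generator.  Defaults define the study
    conditions used throughout the package's tests and experiments."""

    image_size: int = 64
    disc_radius_range: tuple[float, float] = (13.0, 17.0)
    healthy_cdr_range: tuple[float, float] = (0.3, 0.5)
    glaucoma_cdr_range: tuple[float, float] = (0.6, 0.8)
    rim_loss_sector: Optional[str] = None
    rim_loss_strength: float = 0.0
    texture_noise_sd: float = 0.02
    vessel_count: int = 3
    laterality_probability: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("healthy_cdr_range", self.healthy_cdr_range),
            ("glaucoma_cdr_range", self.glaucoma_cdr_range),
        ):
            if not (0.0 < lo < hi < 1.0):
                raise ConfigurationError(f"{name} must satisfy 0 < lo < hi < 1")
        if self.rim_loss_sector is None and self.glaucoma_cdr_range[0] < self.healthy_cdr_range[1]:
            raise ConfigurationError(
                "overlapping CDR ranges require rim_loss_sector to keep classes separable"
            )
        if not (0.0 <= self.rim_loss_strength <= 1.0):
            raise ConfigurationError("rim_loss_strength must lie in [0, 1]")
        if self.image_size < 32:
            raise ConfigurationError("image_size must be at least 32")
        if self.vessel_count < 0:
            raise ConfigurationError("vessel_count must be non-negative")


def _low_frequency_texture(rng, size: int, amplitude: float) -> np.ndarray:
    """Smooth per-channel intensity modulation from an upsampled coarse grid."""
    if amplitude == 0:
        return np.zeros((size, size, 3))
    coarse = rng.normal(0.0, amplitude, size=(8, 8, 3))
    # bilinear upsampling of the coarse grid
    xs = np.linspace(0, 7, size)
    i0 = np.clip(np.floor(xs).astype(int), 0, 6)
    frac = xs - i0
    rows = coarse[i0] * (1 - frac)[:, None, None] + coarse[i0 + 1] * frac[:, None, None]
    cols = rows[:, i0] * (1 - frac)[None, :, None] + rows[:, i0 + 1] * frac[None, :, None]
    return cols


def _draw_vessels(image: np.ndarray, rng, center: tuple[float, float], n: int) -> None:
    """Dark curvilinear tracks radiating from the disc center."""
    size = image.shape[0]
    for _ in range(n):
        theta = rng.uniform(0, 2 * math.pi)
        curvature = rng.uniform(-0.02, 0.02)
        r, c = center
        step_r, step_c = math.sin(theta), math.cos(theta)
        for t in range(int(size * 0.7)):
            rr, cc = int(round(r)), int(round(c))
            if 0 <= rr < size and 0 <= cc < size:
                image[max(rr - 1, 0) : rr + 1, max(cc - 1, 0) : cc + 1] = _VESSEL
            # rotate the direction slightly for curvature
            step_r, step_c = (
                step_r + curvature * step_c,
                step_c - curvature * step_r,
            )
            norm = math.hypot(step_r, step_c)
            r += step_r / norm
            c += step_c / norm


def _sample_cdr(rng, cdr_range: tuple[float, float]) -> float:
    lo, hi = cdr_range
    margin = min(_CDR_RASTER_MARGIN, (hi - lo) / 4)
    return float(rng.uniform(lo + margin, hi - margin))


def _calibrate_cup_scale(
    disc: Ellipse, disc_mask: np.ndarray, target_cdr: float, shape: tuple[int, int]
) -> float:
    """Bisect the cup/disc axis ratio so the mask-measured CDR hits the target.

    Rasterization quantizes areas, so the nominal axis ratio can measure a
    few hundredths off at desk-scale disc sizes; the measured CDR is
    monotone in the cup scale, which makes bisection reliable.
    """
    lo, hi = max(target_cdr - 0.08, 0.05), min(target_cdr + 0.08, 0.98)
    disc_area = disc_mask.sum()
    for _ in range(12):
        mid = (lo + hi) / 2
        cup = Ellipse(disc.center_row, disc.center_col,
                      mid * disc.semi_axis_row, mid * disc.semi_axis_col)
        measured = math.sqrt((cup.rasterize(shape) & disc_mask).sum() / disc_area)
        if measured < target_cdr:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _generate_one(
    config: GeneratorConfig,
    label: int,
    rng: np.random.Generator,
    sample_id: str,
    scheme: SectorScheme,
) -> tuple[FundusSample, DiscCupAnnotation]:
    size = config.image_size
    disc_r = rng.uniform(*config.disc_radius_range)
    aspect = rng.uniform(0.9, 1.1)  # mild ellipticity
    cdr_range = config.glaucoma_cdr_range if label == GLAUCOMA else config.healthy_cdr_range
    cdr = _sample_cdr(rng, cdr_range)
    # disc-centered framing with a small jitter
    center_r = size / 2 + rng.uniform(-2, 2)
    center_c = size / 2 + rng.uniform(-2, 2)
    laterality = "OS" if rng.uniform() < config.laterality_probability else "OD"

    disc = Ellipse(center_r, center_c, disc_r * aspect, disc_r / aspect)
    shape = (size, size)
    disc_mask = disc.rasterize(shape)
    cdr = _calibrate_cup_scale(disc, disc_mask, cdr, shape)
    cup_center_r, cup_center_c = center_r, center_c
    if config.rim_loss_sector is not None and label == GLAUCOMA:
        # displace the cup toward the sector's mid-angle: rim thins there
        theta = math.radians(scheme.mid_angle(config.rim_loss_sector))
        gap = disc_r - cdr * disc_r
        shift = config.rim_loss_strength * gap
        # OD frame: temporal axis points toward the image left, superior up
        d_col = -math.cos(theta) if OD_TEMPORAL_SIDE == "left" else math.cos(theta)
        d_row = -math.sin(theta)
        cup_center_r += shift * d_row
        cup_center_c += shift * d_col
    cup = Ellipse(cup_center_r, cup_center_c, cdr * disc_r * aspect, cdr * disc_r / aspect)
    annotation = DiscCupAnnotation(disc=disc, cup=cup, laterality="OD")

    image = np.tile(_BACKGROUND, (size, size, 1)).astype(float)
    image += _low_frequency_texture(rng, size, 3 * config.texture_noise_sd)
    image[disc_mask] = _DISC
    image[annotation.cup_mask(shape)] = _CUP
    _draw_vessels(image, rng, (center_r, center_c), config.vessel_count)
    if config.texture_noise_sd > 0:
        image += rng.normal(0.0, config.texture_noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    if laterality == "OS":
        image = image[:, ::-1].copy()
        annotation = annotation.mirrored(size)

    sample = FundusSample(image=image, laterality=laterality, label=label, sample_id=sample_id)
    return sample, annotation


def generate_dataset(
    config: GeneratorConfig,
    n_per_class: int,
    scheme: Optional[SectorScheme] = None,
) -> tuple[list[FundusSample], list[DiscCupAnnotation], pd.DataFrame]:
    """Generate a balanced two-class dataset with paired annotations.

    Returns ``(samples, annotations, manifest)``; the manifest row order is
    the canonical image order used by every downstream vectorization.
    """
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be at least 1")
    scheme = scheme or SectorScheme.garway_heath()
    samples, annotations, rows = [], [], []
    seeds = np.random.SeedSequence(config.seed).spawn(2 * n_per_class)
    index = 0
    for label in (HEALTHY, GLAUCOMA):
        for i in range(n_per_class):
            rng = np.random.default_rng(seeds[index])
            sample_id = f"{LABELS[label]}-{i:04d}"
            sample, annotation = _generate_one(config, label, rng, sample_id, scheme)
            samples.append(sample)
            annotations.append(annotation)
            rows.append(
                {
                    "sample_id": sample_id,
                    "laterality": sample.laterality,
                    "label": LABELS[label],
                }
            )
            index += 1
    manifest = pd.DataFrame(rows)
    return samples, annotations, manifest


# ---------------------------------------------------------------------------
# Splits


@dataclass
class SplitSpec:
    """Held-out test ids plus k (train, validation) folds over the rest."""

    test_ids: list[str]
    folds: list[tuple[list[str], list[str]]]
    seed: int


def make_splits(manifest: pd.DataFrame, test_fraction: float, k: int, seed: int) -> SplitSpec:
    """Stratified test split (round-to-nearest size) and stratified k folds."""
    if not (0.0 < test_fraction < 1.0):
        raise ConfigurationError("test_fraction must lie in (0, 1)")
    if k < 2:
        raise ConfigurationError("k must be at least 2")
    if manifest.empty:
        raise ConfigurationError("manifest is empty")
    rng = np.random.default_rng(seed)
    n = len(manifest)
    n_test = int(round(test_fraction * n))
    # largest-remainder allocation of the test quota across classes
    by_class = {lab: manifest.index[manifest["label"] == lab].to_numpy() for lab in LABELS}
    quotas = {lab: test_fraction * len(idx) for lab, idx in by_class.items() if len(idx)}
    base = {lab: int(math.floor(q)) for lab, q in quotas.items()}
    remainder = n_test - sum(base.values())
    order = sorted(quotas, key=lambda lab: quotas[lab] - base[lab], reverse=True)
    for lab in order[:remainder]:
        base[lab] += 1
    test_ids: list[str] = []
    rest_idx: list[int] = []
    for lab, idx in by_class.items():
        perm = rng.permutation(len(idx))
        chosen = idx[perm[: base.get(lab, 0)]]
        test_ids.extend(manifest.loc[chosen, "sample_id"])
        rest_idx.extend(idx[perm[base.get(lab, 0) :]])
    rest = manifest.loc[sorted(rest_idx)]
    counts = rest["label"].value_counts()
    if counts.min() < k:
        raise ConfigurationError("k exceeds the per-class count of non-test samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    ids = rest["sample_id"].to_numpy()
    labels = rest["label"].to_numpy()
    for train_pos, val_pos in skf.split(ids, labels):
        folds.append((list(ids[train_pos]), list(ids[val_pos])))
    return SplitSpec(test_ids=sorted(test_ids), folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# Labels, metrics, training


def randomize_labels(labels: Sequence[int], fraction: float, seed: int) -> np.ndarray:
    """Flip exactly round(fraction * n) binary labels, chosen uniformly."""
    if not (0.0 < fraction <= 1.0):
        raise ConfigurationError("fraction must lie in (0, 1]")
    labels = np.asarray(labels).copy()
    n_flip = int(round(fraction * len(labels)))
    rng = np.random.default_rng(seed)
    flip = rng.choice(len(labels), size=n_flip, replace=False)
    labels[flip] = 1 - labels[flip]
    return labels


def balanced_accuracy(predictions: Sequence[int], truth: Sequence[int]) -> float:
    """Arithmetic mean of sensitivity and specificity."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if len(truth) == 0:
        raise ConfigurationError("empty inputs")
    if set(np.unique(truth)) != {HEALTHY, GLAUCOMA}:
        raise ConfigurationError("both classes must be present in the ground truth")
    sens = np.mean(predictions[truth == GLAUCOMA] == GLAUCOMA)
    spec = np.mean(predictions[truth == HEALTHY] == HEALTHY)
    return float((sens + spec) / 2)


def train_toy_model(
    samples: Sequence[FundusSample] | np.ndarray,
    labels: Sequence[int],
    hyperparams: Optional[Hyperparams] = None,
    seed: int = 0,
) -> ModelAdapter:
    """Train the toy CNN and wrap it in the adapter contract.

    Fixed seed implies identical weights; the training curve is attached to
    the returned adapter as ``.history``.
    """
    images = np.stack([getattr(s, "image", s) for s in samples]).astype(float)
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < 2:
        raise ConfigurationError("need at least two samples of each class")
    hp = hyperparams or Hyperparams()
    net = ToyCNN(images.shape[1], n_classes=2, hyperparams=hp, seed=seed)
    history = fit(net, images, labels, seed=seed)
    return ModelAdapter(net, history=history, model_id=f"toy-seed{seed}")
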