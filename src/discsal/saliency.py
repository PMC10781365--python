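"""Nine attribution methods against the ModelAdapter contract.

Every method explains the model's *predicted* class for the given image —
whether or not that prediction is correct — and returns a single-channel
:class:`SaliencyMap` aligned to the input.  Gradient-based methods reduce
the 3-channel input gradient to one channel as the last step (default: max
of absolute values across channels).

Abbreviations follow the field's usual naming:

====== ===============================
Grad   Gradient (vanilla backprop)
GBack  Guided Backpropagation
SGrad  SmoothGrad
SGrad2 SmoothGrad Squared
VGrad  VarGrad
IGrad  Integrated Gradients
Occl   Occlusion
GCam   GradCAM
SCam   ScoreCAM
====== ===============================
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.transform import resize

from .core import ConfigurationError, ContractError, FundusSample, NumericalError
from .nn import ModelAdapter

METHOD_NAMES = ("Grad", "GBack", "SGrad", "SGrad2", "VGrad", "IGrad", "Occl", "GCam", "SCam")

#: Methods retained after the label-randomization sanity check (GBack and
#: SCam are computed on request but excluded from default analyses).
RETAINED_METHODS = ("Grad", "SGrad", "SGrad2", "VGrad", "IGrad", "Occl", "GCam")


@dataclass
class SaliencyMap:
    """One 2-D relevance field per (model, image, method)."""

    values: np.ndarray  # H x W, finite
    method: str
    target_class: int
    sample_id: str = ""
    native_resolution: Optional[tuple[int, int]] = None
    native_values: Optional[np.ndarray] = None  # pre-upsampling map for CAM methods


@dataclass(frozen=True)
class SaliencyConfig:
    """Shared knobs of the attribution methods.

    ``sg_noise_sd`` is a fraction of the input's dynamic range; ``occl_fill``
    of None means the per-image mean intensity.
    """

    score_view: str = "logit"  # or "probability"
    channel_reduction: str = "max_abs"  # max_abs | mean_abs | sum_then_abs
    sg_samples: int = 25
    sg_noise_sd: float = 0.15
    ig_baseline: str = "black"  # black | white | uniform_random
    ig_steps: int = 50
    occl_patch: Optional[int] = None  # None: ceil(min(H, W) / 14)
    occl_stride: Optional[int] = None  # None: ceil(patch / 2)
    occl_fill: Optional[float] = None  # None: per-image mean intensity
    cam_upsampling: str = "bilinear"  # bilinear | nearest
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sg_samples < 1:
            raise ConfigurationError("sg_samples must be >= 1")
        if self.ig_steps < 1:
            raise ConfigurationError("ig_steps must be >= 1")
        if self.score_view not in ("logit", "probability"):
            raise ConfigurationError("score_view must be 'logit' or 'probability'")
        if self.channel_reduction not in ("max_abs", "mean_abs", "sum_then_abs"):
            raise ConfigurationError(f"unknown channel_reduction {self.channel_reduction!r}")


def _image_of(image) -> tuple[np.ndarray, str]:
    if isinstance(image, FundusSample):
        return image.image, image.sample_id
    return np.asarray(image, dtype=float), ""


def channel_reduce(grad3: np.ndarray, how: str) -> np.ndarray:
    """Collapse an H x W x 3 attribution to a single channel."""
    if how == "max_abs":
        return np.abs(grad3).max(axis=-1)
    if how == "mean_abs":
        return np.abs(grad3).mean(axis=-1)
    if how == "sum_then_abs":
        return np.abs(grad3.sum(axis=-1))
    raise ConfigurationError(f"unknown channel_reduction {how!r}")


def _check_finite(values: np.ndarray, method: str) -> np.ndarray:
    if not np.all(np.isfinite(values)):
        raise NumericalError(f"{method} produced non-finite values")
    return values


def _upsample(native: np.ndarray, shape: tuple[int, int], how: str) -> np.ndarray:
    if native.shape == tuple(shape):
        return native
    if how == "nearest":
        h, w = native.shape
        if shape[0] % h == 0 and shape[1] % w == 0:
            return np.kron(native, np.ones((shape[0] // h, shape[1] // w)))
        return resize(native, shape, order=0, anti_aliasing=False, preserve_range=True)
    if how == "bilinear":
        return resize(native, shape, order=1, anti_aliasing=False, preserve_range=True)
    raise ConfigurationError(f"unknown cam_upsampling {how!r}")


# ---------------------------------------------------------------------------
# Gradient family


def grad_map(model: ModelAdapter, image, config: SaliencyConfig = SaliencyConfig()) -> SaliencyMap:
    """Vanilla gradient of the predicted-class score with respect to the input."""
    x, sid = _image_of(image)
    k = model.predicted_class(x)
    g = model.input_gradient(x, k, score_view=config.score_view)
    values = _check_finite(channel_reduce(g, config.channel_reduction), "Grad")
    return SaliencyMap(values=values, method="Grad", target_class=k, sample_id=sid)


def guided_backprop_map(model: ModelAdapter, image,
                        config: SaliencyConfig = SaliencyConfig()) -> SaliencyMap:
    """Gradient with the guided rule: ReLUs also block negative upstream gradients."""
    if not getattr(model, "relu_override", False):
        raise ContractError("GBack requires an adapter with the guided-ReLU override")
    x, sid = _image_of(image)
    k = model.predicted_class(x)
    g = model.input_gradient(x, k, score_view=config.score_view, guided=True)
    values = _check_finite(channel_reduce(g, config.channel_reduction), "GBack")
    return SaliencyMap(values=values, method="GBack", target_class=k, sample_id=sid)


def smoothgrad_map(model: ModelAdapter, image, config: SaliencyConfig = SaliencyConfig(),
                   mode: str = "mean") -> SaliencyMap:
    """Noise-averaged gradients: mean (SGrad), squared (SGrad2) or variance (VGrad).

    Gaussian noise with sd equal to ``sg_noise_sd`` times the input's dynamic
    range is added before each of ``sg_samples`` gradient evaluations; the
    per-channel aggregate is channel-reduced last.
    """
    names = {"mean": "SGrad", "squared": "SGrad2", "variance": "VGrad"}
    if mode not in names:
        raise ConfigurationError(f"unknown SmoothGrad mode {mode!r}")
    name = names[mode]
    x, sid = _image_of(image)
    k = model.predicted_class(x)
    n = config.sg_samples
    if mode == "variance" and n == 1:
        warnings.warn("VGrad with a single sample is identically zero")
        return SaliencyMap(values=np.zeros(x.shape[:2]), method=name, target_class=k,
                           sample_id=sid)
    sd = config.sg_noise_sd * (x.max() - x.min())
    rng = np.random.default_rng(config.seed)
    if sd > 0:
        batch = x[None] + rng.normal(0.0, sd, size=(n,) + x.shape)
    else:
        # all noise draws coincide with the input: one evaluation suffices and
        # keeps the zero-noise limit exactly equal to the plain gradient
        batch = x[None]
    grads = model.input_gradient(batch, k, score_view=config.score_view)
    if mode == "mean":
        agg = grads.mean(axis=0)
    elif mode == "squared":
        agg = (grads**2).mean(axis=0)
    else:
        agg = grads.var(axis=0)
    values = _check_finite(channel_reduce(agg, config.channel_reduction), name)
    return SaliencyMap(values=values, method=name, target_class=k, sample_id=sid)


def integrated_gradients_attributions(
    model: ModelAdapter, image, config: SaliencyConfig = SaliencyConfig()
) -> tuple[np.ndarray, np.ndarray, int]:
    """Signed per-channel integrated gradients plus the baseline used.

    Riemann approximation over ``ig_steps`` points on the straight path from
    the baseline to the input, multiplied elementwise by (input − baseline).
    Returns ``(signed H x W x 3 attributions, baseline, target class)``; the
    signed tensor supports the completeness check before channel reduction.
    """
    x, _ = _image_of(image)
    k = model.predicted_class(x)
    if config.ig_baseline == "black":
        baseline = np.zeros_like(x)
    elif config.ig_baseline == "white":
        baseline = np.ones_like(x)
    elif config.ig_baseline == "uniform_random":
        baseline = np.random.default_rng(config.seed).uniform(size=x.shape)
    else:
        baseline = np.asarray(config.ig_baseline, dtype=float)
        if baseline.shape != x.shape:
            raise ConfigurationError("IGrad baseline shape does not match the image")
    m = config.ig_steps
    alphas = (np.arange(m) + 0.5) / m  # midpoint rule
    batch = baseline[None] + alphas[:, None, None, None] * (x - baseline)[None]
    grads = model.input_gradient(batch, k, score_view=config.score_view)
    attr = grads.mean(axis=0) * (x - baseline)
    return attr, baseline, k


def integrated_gradients_map(model: ModelAdapter, image,
                             config: SaliencyConfig = SaliencyConfig()) -> SaliencyMap:
    """Integrated gradients, channel-reduced to a single-channel map."""
    x, sid = _image_of(image)
    attr, _, k = integrated_gradients_attributions(model, image, config)
    values = _check_finite(channel_reduce(attr, config.channel_reduction), "IGrad")
    return SaliencyMap(values=values, method="IGrad", target_class=k, sample_id=sid)


# ---------------------------------------------------------------------------
# Perturbation / CAM family


def _occlusion_positions(extent: int, patch: int, stride: int) -> list[int]:
    pos = list(range(0, extent - patch + 1, stride))
    if pos[-1] != extent - patch:
        pos.append(extent - patch)  # tail window so every pixel is covered
    return pos


def occlusion_map(model: ModelAdapter, image,
                  config: SaliencyConfig = SaliencyConfig()) -> SaliencyMap:
    """Score drop under a sliding uniform square; per-pixel mean over windows.

    Each window's contribution is score(original) − score(occluded) for the
    predicted class; a pixel's saliency is the mean contribution over all
    windows covering it.
    """
    x, sid = _image_of(image)
    h, w = x.shape[:2]
    patch = config.occl_patch or math.ceil(min(h, w) / 14)
    stride = config.occl_stride or math.ceil(patch / 2)
    if not (1 <= patch <= min(h, w)):
        raise ConfigurationError("occl_patch must lie in [1, min(H, W)]")
    if not (1 <= stride <= patch):
        raise ConfigurationError("occl_stride must lie in [1, occl_patch]")
    fill = float(x.mean()) if config.occl_fill is None else float(config.occl_fill)
    k = model.predicted_class(x)
    s0 = float(model.scores(x, k, score_view=config.score_view))

    windows = [(r, c) for r in _occlusion_positions(h, patch, stride)
               for c in _occlusion_positions(w, patch, stride)]
    contrib = np.zeros((h, w))
    count = np.zeros((h, w))
    chunk = 64
    for start in range(0, len(windows), chunk):
        part = windows[start : start + chunk]
        batch = np.repeat(x[None], len(part), axis=0)
        for i, (r, c) in enumerate(part):
            batch[i, r : r + patch, c : c + patch, :] = fill
        scores = model.scores(batch, k, score_view=config.score_view)
        for (r, c), s in zip(part, scores):
            contrib[r : r + patch, c : c + patch] += s0 - s
            count[r : r + patch, c : c + patch] += 1
    values = _check_finite(contrib / count, "Occl")
    return SaliencyMap(values=values, method="Occl", target_class=k, sample_id=sid)


def gradcam_map(model: ModelAdapter, image,
                config: SaliencyConfig = SaliencyConfig()) -> SaliencyMap:
    """ReLU of the gradient-weighted sum of CAM-layer feature maps."""
    x, sid = _image_of(image)
    if not hasattr(model, "cam_layer_activations"):
        raise ContractError("GCam requires an adapter with a designated CAM layer")
    k = model.predicted_class(x)
    acts = model.cam_layer_activations(x)  # h x w x C
    grads = model.cam_layer_gradients(x, k, score_view=config.score_view)
    weights = grads.mean(axis=(0, 1))  # spatial mean per channel
    native = np.maximum((acts * weights).sum(axis=-1), 0.0)
    values = _upsample(native, x.shape[:2], config.cam_upsampling)
    _check_finite(values, "GCam")
    return SaliencyMap(values=values, method="GCam", target_class=k, sample_id=sid,
                       native_resolution=native.shape, native_values=native)


def scorecam_map(model: ModelAdapter, image,
                 config: SaliencyConfig = SaliencyConfig()) -> SaliencyMap:
    """Gradient-free CAM: activation maps as input masks, scores as weights.

    Each CAM-layer activation map is min-max normalized, upsampled to the
    input size and used to modulate the input; the predicted-class score of
    the masked input is that channel's weight.  Constant activation maps are
    skipped (their normalization is undefined).
    """
    x, sid = _image_of(image)
    if not hasattr(model, "cam_layer_activations"):
        raise ContractError("SCam requires an adapter with a designated CAM layer")
    k = model.predicted_class(x)
    acts = model.cam_layer_activations(x)  # h x w x C
    n_ch = acts.shape[-1]
    weights = np.zeros(n_ch)
    used = np.zeros(n_ch, dtype=bool)
    masked_batch = []
    kept = []
    for c in range(n_ch):
        a = acts[..., c]
        if a.max() == a.min():
            warnings.warn(f"SCam: constant activation map in channel {c}, skipped")
            continue
        norm = (a - a.min()) / (a.max() - a.min())
        mask = _upsample(norm, x.shape[:2], config.cam_upsampling)
        masked_batch.append(x * mask[..., None])
        kept.append(c)
    if kept:
        scores = model.scores(np.stack(masked_batch), k, score_view=config.score_view)
        weights[kept] = np.atleast_1d(scores)
        used[kept] = True
    native = np.maximum((acts[..., used] * weights[used]).sum(axis=-1), 0.0)
    values = _upsample(native, x.shape[:2], config.cam_upsampling)
    _check_finite(values, "SCam")
    return SaliencyMap(values=values, method="SCam", target_class=k, sample_id=sid,
                       native_resolution=native.shape, native_values=native)


def compute_map(method: str, model: ModelAdapter, image,
                config: SaliencyConfig = SaliencyConfig()) -> SaliencyMap:
    """Dispatch a method by its abbreviated name."""
    dispatch = {
        "Grad": grad_map,
        "GBack": guided_backprop_map,
        "SGrad": lambda m, i, c: smoothgrad_map(m, i, c, mode="mean"),
        "SGrad2": lambda m, i, c: smoothgrad_map(m, i, c, mode="squared"),
        "VGrad": lambda m, i, c: smoothgrad_map(m, i, c, mode="variance"),
        "IGrad": integrated_gradients_map,
        "Occl": occlusion_map,
        "GCam": gradcam_map,
        "SCam": scorecam_map,
    }
    if method not in dispatch:
        raise ConfigurationError(f"unknown saliency method {method!r}")
    return dispatch[method](model, image, config)
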