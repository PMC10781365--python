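"""A compact differentiable convolutional network in pure numpy.

The attribution methods in this package need more access to a classifier's
internals than an inference API exposes: gradients with respect to the
input, activations and gradients at a designated convolutional (CAM) layer,
a guided-ReLU backward rule, and cheap reinitialization for randomization
sanity checks.  This module implements exactly that contract for a small
conv-net (strided 3x3 convolutions + ReLU, global average pooling, dense
head) with hand-written forward/backward passes in float64.

Array layout is channels-last throughout: images are (B, H, W, C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import ConfigurationError, ContractError


# ---------------------------------------------------------------------------
# im2col plumbing


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    """View the padded input as (B, oh, ow, kh, kw, C) patch array."""
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    b, h, w, c = xp.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    s0, s1, s2, s3 = xp.strides
    shape = (b, oh, ow, kh, kw, c)
    strides = (s0, s1 * stride, s2 * stride, s1, s2, s3)
    return np.lib.stride_tricks.as_strided(xp, shape, strides), xp.shape


def _col2im(dcols: np.ndarray, padded_shape, stride: int, pad: int) -> np.ndarray:
    """Scatter patch gradients back onto the (unpadded) input."""
    b, hp, wp, c = padded_shape
    _, oh, ow, kh, kw, _ = dcols.shape
    dxp = np.zeros((b, hp, wp, c))
    for i in range(kh):
        for j in range(kw):
            dxp[:, i : i + oh * stride : stride, j : j + ow * stride : stride, :] += dcols[
                :, :, :, i, j, :
            ]
    if pad:
        return dxp[:, pad:-pad, pad:-pad, :]
    return dxp


# ---------------------------------------------------------------------------
# Layers


class Conv2D:
    """3x3-style convolution with stride and symmetric zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, pad: int, rng):
        fan_in = kernel * kernel * c_in
        self.w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(kernel, kernel, c_in, c_out))
        self.b = np.zeros(c_out)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, padded_shape = _im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        b, oh, ow = cols.shape[:3]
        flat = cols.reshape(b, oh, ow, -1)
        y = flat @ self.w.reshape(-1, self.w.shape[-1]) + self.b
        self._cache = (flat, padded_shape, (b, oh, ow))
        return y

    def backward(self, gy: np.ndarray, accumulate: bool = False):
        flat, padded_shape, (b, oh, ow) = self._cache
        wmat = self.w.reshape(-1, self.w.shape[-1])
        gw = np.einsum("bijk,bijo->ko", flat, gy).reshape(self.w.shape)
        gb = gy.sum(axis=(0, 1, 2))
        gflat = gy @ wmat.T
        dcols = gflat.reshape(b, oh, ow, self.kernel, self.kernel, -1)
        gx = _col2im(dcols, padded_shape, self.stride, self.pad)
        if accumulate:
            self.gw, self.gb = gw, gb
        return gx


class ReLU:
    def __init__(self):
        self._mask = None

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray, guided: bool = False) -> np.ndarray:
        g = np.where(self._mask, gy, 0.0)
        if guided:
            # guided backprop: additionally zero negative upstream gradients
            g = np.where(g > 0, g, 0.0)
        return g


class GlobalAvgPool:
    def __init__(self):
        self._shape = None

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        return np.broadcast_to(gy[:, None, None, :], self._shape) / (h * w)


class Dense:
    def __init__(self, c_in: int, c_out: int, rng):
        self.w = rng.normal(0.0, math.sqrt(2.0 / c_in), size=(c_in, c_out))
        self.b = np.zeros(c_out)
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.w + self.b

    def backward(self, gy: np.ndarray, accumulate: bool = False):
        x = self._cache
        gw = x.T @ gy
        gb = gy.sum(axis=0)
        gx = gy @ self.w.T
        if accumulate:
            self.gw, self.gb = gw, gb
        return gx


# ---------------------------------------------------------------------------
# Network


@dataclass
class Hyperparams:
    """Training and architecture knobs for the toy classifier."""

    channels: tuple[int, ...] = (8, 16, 32)
    kernel: int = 3
    stride: int = 2
    epochs: int = 120
    learning_rate: float = 1e-2
    batch_size: int = 32
    use_relu: bool = True  # disabled only for linear-model oracles in tests


class ToyCNN:
    """Strided-conv classifier; the last conv's post-ReLU output is the CAM layer."""

    def __init__(self, image_size: int, n_classes: int = 2, hyperparams: Hyperparams | None = None,
                 seed: int = 0):
        hp = hyperparams or Hyperparams()
        if not hp.channels:
            raise ConfigurationError("at least one convolutional layer is required")
        self.image_size = image_size
        self.n_classes = n_classes
        self.hp = hp
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.layers: list = []
        c_in = 3
        for c_out in hp.channels:
            self.layers.append(Conv2D(c_in, c_out, hp.kernel, hp.stride, hp.kernel // 2, rng))
            if hp.use_relu:
                self.layers.append(ReLU())
            c_in = c_out
        # CAM tap: output of the last conv block (post-activation)
        self.cam_index = len(self.layers) - 1
        self.layers.append(GlobalAvgPool())
        self.layers.append(Dense(c_in, n_classes, rng))
        self.has_relu = hp.use_relu

    # -- forward / backward -------------------------------------------------

    #: subtracted from inputs before the first convolution; centering the
    #: all-positive intensities conditions the optimization and does not
    #: change any input gradient (the offset has derivative 1)
    input_offset = 0.5

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for a (B, H, W, 3) batch; caches activations for backward."""
        h = x - self.input_offset
        self._cam_activation = None
        for i, layer in enumerate(self.layers):
            h = layer.forward(h)
            if i == self.cam_index:
                self._cam_activation = h
        return h

    def backward(self, glogits: np.ndarray, guided: bool = False,
                 to_cam: bool = False, accumulate: bool = False) -> np.ndarray:
        """Backpropagate d(score)/d(logits) to the input (or the CAM tap)."""
        g = glogits
        for i in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[i]
            if to_cam and i == self.cam_index:
                return g  # gradient w.r.t. the tapped (post-activation) output
            if isinstance(layer, ReLU):
                g = layer.backward(g, guided=guided)
            elif isinstance(layer, (Conv2D, Dense)):
                g = layer.backward(g, accumulate=accumulate)
            else:
                g = layer.backward(g)
        return g

    # -- parameter access ---------------------------------------------------

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def grads(self):
        out = []
        for layer in self.layers:
            if isinstance(layer, (Conv2D, Dense)):
                out.extend([layer.gw, layer.gb])
        return out

    def get_weights(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.copy() for i, p in enumerate(self.parameters())}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ConfigurationError("weight count mismatch")
        for i, p in enumerate(params):
            p[...] = weights[f"p{i}"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def fit(net: ToyCNN, images: np.ndarray, labels: np.ndarray, seed: int = 0) -> list[dict]:
    """Adam + categorical cross-entropy; returns the per-epoch training curve."""
    hp = net.hp
    rng = np.random.default_rng(seed)
    params = net.parameters()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    n = len(images)
    history = []
    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            xb, yb = images[idx], labels[idx]
            logits = net.forward(xb)
            p = softmax(logits)
            loss = -np.mean(np.log(p[np.arange(len(idx)), yb] + 1e-12))
            glogits = p.copy()
            glogits[np.arange(len(idx)), yb] -= 1.0
            glogits /= len(idx)
            net.backward(glogits, accumulate=True)
            t += 1
            for i, (param, g) in enumerate(zip(params, net.grads())):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g * g
                mhat = m[i] / (1 - beta1**t)
                vhat = v[i] / (1 - beta2**t)
                param -= hp.learning_rate * mhat / (np.sqrt(vhat) + eps)
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == yb).sum())
        history.append({"epoch": epoch, "loss": float(np.mean(losses)), "accuracy": correct / n})
    return history


# ---------------------------------------------------------------------------
# Model adapter


class ModelAdapter:
    """Uniform differentiable-classifier interface consumed by every attribution method.

    Wraps a :class:`ToyCNN` and exposes prediction, input gradients (with an
    optional guided-ReLU rule), CAM-layer taps and seeded reinitialization.
    """

    relu_override = True

    def __init__(self, net: ToyCNN, history: Optional[list] = None, model_id: str = "model"):
        self.net = net
        self.history = history or []
        self.model_id = model_id
        self.relu_override = net.has_relu

    @property
    def n_classes(self) -> int:
        return self.net.n_classes

    # -- prediction ---------------------------------------------------------

    @staticmethod
    def _batched(x: np.ndarray) -> tuple[np.ndarray, bool]:
        if x.ndim == 3:
            return x[None], True
        return x, False

    def predict(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(logits, probabilities) for a (B, H, W, 3) batch or single image."""
        x, single = self._batched(np.asarray(images, dtype=float))
        logits = self.net.forward(x)
        probs = softmax(logits)
        if single:
            return logits[0], probs[0]
        return logits, probs

    def predicted_class(self, image: np.ndarray) -> int:
        logits, _ = self.predict(image)
        return int(np.argmax(logits))

    def scores(self, images: np.ndarray, class_index: int, score_view: str = "logit") -> np.ndarray:
        x, single = self._batched(np.asarray(images, dtype=float))
        logits = self.net.forward(x)
        if score_view == "logit":
            s = logits[:, class_index]
        elif score_view == "probability":
            s = softmax(logits)[:, class_index]
        else:
            raise ConfigurationError(f"unknown score_view {score_view!r}")
        return s[0] if single else s

    # -- gradients ----------------------------------------------------------

    def _score_grad_wrt_logits(self, logits: np.ndarray, class_index: int,
                               score_view: str) -> np.ndarray:
        g = np.zeros_like(logits)
        if score_view == "logit":
            g[:, class_index] = 1.0
        elif score_view == "probability":
            p = softmax(logits)
            onehot = np.zeros_like(logits)
            onehot[:, class_index] = 1.0
            g = p[:, class_index : class_index + 1] * (onehot - p)
        else:
            raise ConfigurationError(f"unknown score_view {score_view!r}")
        return g

    def input_gradient(self, image: np.ndarray, class_index: int,
                       score_view: str = "logit", guided: bool = False) -> np.ndarray:
        """d(score)/d(input), shape H x W x 3 (or batched)."""
        if guided and not self.relu_override:
            raise ContractError("adapter does not support the guided-ReLU override")
        x, single = self._batched(np.asarray(image, dtype=float))
        logits = self.net.forward(x)
        g = self.net.backward(self._score_grad_wrt_logits(logits, class_index, score_view),
                              guided=guided)
        return g[0] if single else g

    def cam_layer_activations(self, image: np.ndarray) -> np.ndarray:
        """Post-activation feature maps of the CAM layer, shape h x w x C."""
        x, single = self._batched(np.asarray(image, dtype=float))
        self.net.forward(x)
        a = self.net._cam_activation
        return a[0] if single else a

    def cam_layer_gradients(self, image: np.ndarray, class_index: int,
                            score_view: str = "logit") -> np.ndarray:
        """d(score)/d(CAM activations), shape h x w x C."""
        x, single = self._batched(np.asarray(image, dtype=float))
        logits = self.net.forward(x)
        g = self.net.backward(self._score_grad_wrt_logits(logits, class_index, score_view),
                              to_cam=True)
        return g[0] if single else g

    def reinitialize(self, seed: int) -> "ModelAdapter":
        """Fresh untrained copy of the same architecture."""
        net = ToyCNN(self.net.image_size, self.net.n_classes, self.net.hp, seed=seed)
        return ModelAdapter(net, model_id=f"{self.model_id}-reinit{seed}")
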