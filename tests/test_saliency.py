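"""Attribution methods against independent oracles (finite differences,
hand-rolled chain rules, exhaustive enumeration, closed forms)."""

import math

import numpy as np
import pytest

from discsal.core import ContractError
from discsal.nn import Hyperparams, ModelAdapter, ToyCNN
from discsal.saliency import (
    METHOD_NAMES,
    SaliencyConfig,
    channel_reduce,
    compute_map,
    grad_map,
    gradcam_map,
    guided_backprop_map,
    integrated_gradients_attributions,
    integrated_gradients_map,
    occlusion_map,
    scorecam_map,
    smoothgrad_map,
)

from conftest import make_linear_adapter, make_tiny_adapter


@pytest.fixture(scope="module")
def probe_image():
    return np.random.default_rng(42).uniform(size=(8, 8, 3))


@pytest.fixture(scope="module")
def linear():
    return make_linear_adapter(image_size=8, seed=1)


@pytest.fixture(scope="module")
def tiny():
    return make_tiny_adapter(image_size=8, seed=2)


def _linear_weights(adapter, k):
    """Closed-form d(logit_k)/dx for the ReLU-free 1x1-conv + GAP + dense net:
    constant per channel, w_c = (conv row c of W1) @ dense[:, k] / (H*W)."""
    conv = adapter.net.layers[0]
    dense = adapter.net.layers[-1]
    h = w = adapter.net.image_size
    per_channel = conv.w[0, 0] @ dense.w[:, k] / (h * w)  # shape (3,)
    return per_channel


class TestGrad:
    def test_linear_model_gives_constant_weight_map(self, linear, probe_image):
        k = linear.predicted_class(probe_image)
        w = _linear_weights(linear, k)
        smap = grad_map(linear, probe_image)
        assert np.allclose(smap.values, np.abs(w).max())

    def test_constant_model_gives_zero_map(self, probe_image):
        adapter = make_linear_adapter(image_size=8, seed=0)
        for p in adapter.net.parameters():
            p[...] = 0.0
        smap = grad_map(adapter, probe_image)
        assert np.all(smap.values == 0.0)

    def test_matches_finite_differences_on_cnn(self, tiny, probe_image):
        k = tiny.predicted_class(probe_image)
        smap = grad_map(tiny, probe_image)
        g = tiny.input_gradient(probe_image, k)
        eps = 1e-6
        rng = np.random.default_rng(3)
        for _ in range(10):
            i, j, c = rng.integers(0, 8), rng.integers(0, 8), rng.integers(0, 3)
            xp, xm = probe_image.copy(), probe_image.copy()
            xp[i, j, c] += eps
            xm[i, j, c] -= eps
            fd = (tiny.scores(xp, k) - tiny.scores(xm, k)) / (2 * eps)
            assert g[i, j, c] == pytest.approx(fd, rel=1e-3, abs=1e-9)
        assert np.array_equal(smap.values, channel_reduce(g, "max_abs"))

    def test_label_never_changes_the_map(self, tiny, probe_image):
        # attribution explains the predicted class; the true label plays no role
        a = grad_map(tiny, probe_image).values
        b = grad_map(tiny, probe_image).values
        assert np.array_equal(a, b)


class _NaiveGuided:
    """Independent loop-based forward/backward with the guided-ReLU rule."""

    def __init__(self, net):
        self.net = net

    def run(self, x):
        net = self.net
        h = x - net.input_offset
        convs = [l for l in net.layers if hasattr(l, "kernel")]
        acts = []
        in_sizes = []
        for conv in convs:
            in_sizes.append(h.shape[0])
            h = self._conv(h, conv)
            acts.append(h.copy())
            h = np.maximum(h, 0.0)
        pooled = h.mean(axis=(0, 1))
        dense = net.layers[-1]
        logits = pooled @ dense.w + dense.b
        k = int(np.argmax(logits))
        # backward
        gp = dense.w[:, k]
        g = np.ones(h.shape) * gp / (h.shape[0] * h.shape[1])
        for conv, a, in_size in zip(reversed(convs), reversed(acts), reversed(in_sizes)):
            g = np.where(a > 0, g, 0.0)
            g = np.where(g > 0, g, 0.0)  # guided rule
            g = self._conv_T(g, conv, in_size)
        return g

    @staticmethod
    def _conv(x, conv):
        k, s, p = conv.kernel, conv.stride, conv.pad
        xp = np.pad(x, ((p, p), (p, p), (0, 0)))
        oh = (xp.shape[0] - k) // s + 1
        ow = (xp.shape[1] - k) // s + 1
        out = np.zeros((oh, ow, conv.w.shape[-1]))
        for i in range(oh):
            for j in range(ow):
                patch = xp[i * s : i * s + k, j * s : j * s + k, :]
                out[i, j] = np.einsum("abc,abco->o", patch, conv.w) + conv.b
        return out

    @staticmethod
    def _conv_T(g, conv, in_size):
        k, s, p = conv.kernel, conv.stride, conv.pad
        oh, ow, _ = g.shape
        hp = in_size + 2 * p
        gx = np.zeros((hp, hp, conv.w.shape[2]))
        for i in range(oh):
            for j in range(ow):
                gx[i * s : i * s + k, j * s : j * s + k, :] += np.einsum(
                    "o,abco->abc", g[i, j], conv.w
                )
        return gx[p : hp - p, p : hp - p, :]


class TestGuidedBackprop:
    def test_matches_naive_guided_chain_rule(self, probe_image):
        adapter = make_tiny_adapter(image_size=8, seed=5, channels=(2, 3))
        oracle = _NaiveGuided(adapter.net).run(probe_image)
        smap = guided_backprop_map(adapter, probe_image)
        assert np.allclose(smap.values, channel_reduce(oracle, "max_abs"))

    def test_no_relu_network_equals_plain_gradient(self, linear, probe_image):
        linear.relu_override = True  # vacuous: the net has no ReLUs
        a = guided_backprop_map(linear, probe_image).values
        b = grad_map(linear, probe_image).values
        assert np.array_equal(a, b)

    def test_adapter_without_override_rejected(self, tiny, probe_image):
        tiny_no = make_tiny_adapter(image_size=8, seed=2)
        tiny_no.relu_override = False
        with pytest.raises(ContractError):
            guided_backprop_map(tiny_no, probe_image)


class TestSmoothGrad:
    def test_zero_noise_equals_plain_gradient_exactly(self, tiny, probe_image):
        config = SaliencyConfig(sg_noise_sd=0.0, sg_samples=7)
        a = smoothgrad_map(tiny, probe_image, config, mode="mean").values
        b = grad_map(tiny, probe_image, config).values
        assert np.array_equal(a, b)

    def test_single_sample_variance_is_zero(self, tiny, probe_image):
        config = SaliencyConfig(sg_samples=1)
        with pytest.warns(UserWarning):
            smap = smoothgrad_map(tiny, probe_image, config, mode="variance")
        assert np.all(smap.values == 0.0)

    def test_squared_single_sample_zero_noise_is_gradient_squared(self, tiny, probe_image):
        config = SaliencyConfig(sg_samples=1, sg_noise_sd=0.0)
        sq = smoothgrad_map(tiny, probe_image, config, mode="squared").values
        k = tiny.predicted_class(probe_image)
        g = tiny.input_gradient(probe_image, k)
        assert np.allclose(sq, channel_reduce(g**2, "max_abs"))

    def test_seeded_noise_is_reproducible(self, tiny, probe_image):
        config = SaliencyConfig(seed=11)
        a = smoothgrad_map(tiny, probe_image, config).values
        b = smoothgrad_map(tiny, probe_image, config).values
        assert np.array_equal(a, b)


class TestIntegratedGradients:
    def test_image_equal_to_baseline_gives_zero_map(self, tiny):
        black = np.zeros((8, 8, 3))
        smap = integrated_gradients_map(tiny, black, SaliencyConfig(ig_baseline="black"))
        assert np.allclose(smap.values, 0.0)

    def test_linear_model_is_exact_at_any_step_count(self, linear, probe_image):
        for steps in (1, 5):
            attr, baseline, k = integrated_gradients_attributions(
                linear, probe_image, SaliencyConfig(ig_steps=steps)
            )
            w = _linear_weights(linear, k)
            expected = np.broadcast_to(w, probe_image.shape) * (probe_image - baseline)
            assert np.allclose(attr, expected)

    def test_completeness_within_one_percent_on_cnn(self, trained_model, rng):
        x = rng.uniform(size=(64, 64, 3))
        config = SaliencyConfig(ig_steps=256)
        attr, baseline, k = integrated_gradients_attributions(trained_model, x, config)
        delta = trained_model.scores(x, k) - trained_model.scores(baseline, k)
        assert abs(attr.sum() - delta) <= 0.01 * abs(delta)


class TestOcclusion:
    def test_constant_model_gives_zero_map(self, probe_image):
        adapter = make_linear_adapter(image_size=8, seed=0)
        for p in adapter.net.parameters():
            p[...] = 0.0
        smap = occlusion_map(adapter, probe_image)
        assert np.allclose(smap.values, 0.0)

    def test_linear_model_window_closed_form(self, linear, probe_image):
        # one full-image window: contribution = sum_c w_c * sum_p (x_pc - fill)
        config = SaliencyConfig(occl_patch=8, occl_stride=8, occl_fill=0.25)
        k = linear.predicted_class(probe_image)
        w = _linear_weights(linear, k)
        expected = sum(
            w[c] * (probe_image[..., c] - 0.25).sum() for c in range(3)
        )
        smap = occlusion_map(linear, probe_image, config)
        assert np.allclose(smap.values, expected)

    def test_matches_exhaustive_window_enumeration(self, tiny, probe_image):
        config = SaliencyConfig(occl_patch=4, occl_stride=2, occl_fill=0.5)
        smap = occlusion_map(tiny, probe_image, config)
        k = tiny.predicted_class(probe_image)
        s0 = float(tiny.scores(probe_image, k))
        contrib = np.zeros((8, 8))
        count = np.zeros((8, 8))
        positions = [0, 2, 4]
        assert len(positions) ** 2 == 9
        for r in positions:
            for c in positions:
                occluded = probe_image.copy()
                occluded[r : r + 4, c : c + 4, :] = 0.5
                s = float(tiny.scores(occluded, k))
                contrib[r : r + 4, c : c + 4] += s0 - s
                count[r : r + 4, c : c + 4] += 1
        assert np.allclose(smap.values, contrib / count)

    def test_stride_larger_than_patch_rejected(self, tiny, probe_image):
        from discsal.core import ConfigurationError

        with pytest.raises(ConfigurationError):
            occlusion_map(tiny, probe_image, SaliencyConfig(occl_patch=2, occl_stride=3))


class TestGradCAM:
    def test_hand_computed_single_conv_net(self, probe_image):
        adapter = make_linear_adapter(image_size=8, seed=4, channels=(2,))
        k = adapter.predicted_class(probe_image)
        conv = adapter.net.layers[0]
        dense = adapter.net.layers[-1]
        acts = np.einsum("hwc,co->hwo", probe_image - 0.5, conv.w[0, 0]) + conv.b
        weights = dense.w[:, k] / (8 * 8)  # spatial mean of the constant gradient
        expected = np.maximum((acts * weights).sum(-1), 0.0)
        smap = gradcam_map(adapter, probe_image)
        assert np.allclose(smap.values, expected)
        assert smap.native_resolution == (8, 8)

    def test_nonnegative_and_zero_when_weighted_sum_negative(self, tiny, probe_image):
        smap = gradcam_map(tiny, probe_image)
        assert np.all(smap.values >= 0.0)

    def test_nearest_upsampling_gives_constant_blocks(self):
        from discsal.saliency import _upsample

        native = np.array([[1.0, 2.0], [3.0, 4.0]])
        up = _upsample(native, (4, 4), "nearest")
        assert np.array_equal(up, np.kron(native, np.ones((2, 2))))


class TestScoreCAM:
    def test_matches_brute_force_channel_loop(self, probe_image):
        adapter = make_tiny_adapter(image_size=8, seed=7, channels=(2,))
        config = SaliencyConfig()
        smap = scorecam_map(adapter, probe_image, config)
        from discsal.saliency import _upsample

        k = adapter.predicted_class(probe_image)
        acts = adapter.cam_layer_activations(probe_image)
        total = np.zeros(acts.shape[:2])
        for c in range(acts.shape[-1]):
            a = acts[..., c]
            if a.max() == a.min():
                continue
            norm = (a - a.min()) / (a.max() - a.min())
            mask = _upsample(norm, (8, 8), config.cam_upsampling)
            s = float(adapter.scores(probe_image * mask[..., None], k))
            total += s * a
        expected = _upsample(np.maximum(total, 0.0), (8, 8), config.cam_upsampling)
        assert np.allclose(smap.values, expected)

    def test_nonnegative(self, tiny, probe_image):
        assert np.all(scorecam_map(tiny, probe_image).values >= 0.0)


class TestCommonContract:
    @pytest.mark.parametrize("method", METHOD_NAMES)
    def test_shape_finiteness_and_determinism(self, tiny, probe_image, method):
        a = compute_map(method, tiny, probe_image)
        b = compute_map(method, tiny, probe_image)
        assert a.values.shape == probe_image.shape[:2]
        assert np.all(np.isfinite(a.values))
        assert np.array_equal(a.values, b.values)
        assert a.target_class == tiny.predicted_class(probe_image)
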