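"""Closed-form and conservation oracles for the twelve attribution methods."""
from types import SimpleNamespace

import numpy as np
import pytest

from eegxai import attribution as attr
from eegxai._nn import Dense, Flatten, Network, ReLU, TemporalConv, softmax


class ToyDecoder:
    """Minimal decoder-shaped wrapper around a hand-built network."""

    def __init__(self, net, n_classes, scale=1.0):
        self.net_ = net
        self.scale_ = scale
        self.spec_ = SimpleNamespace(n_classes=n_classes)


def linear_decoder(T=6, C=3, n_classes=2, seed=0):
    rng = np.random.default_rng(seed)
    dense = Dense(T * C, n_classes, rng, name="out", dtype=np.float64)
    dense.b[:] = 0
    return ToyDecoder(Network([Flatten(), dense]), n_classes), dense


def relu_toy(seed=0, bias_shift=0.0):
    """Flatten -> Dense -> (single) ReLU -> Dense head."""
    rng = np.random.default_rng(seed)
    d1 = Dense(12, 8, rng, name="dense1", dtype=np.float64)
    d1.b[:] = bias_shift
    d2 = Dense(8, 3, rng, name="out", dtype=np.float64)
    return ToyDecoder(Network([Flatten(), d1, ReLU(name="relu_h"), d2]), 3), d1, d2


class TestGradientMethods:
    def test_saliency_of_linear_model_is_weight_row(self):
        dec, dense = linear_decoder()
        x = np.random.default_rng(1).standard_normal((6, 3))
        R = attr.saliency(dec, x, 1, absolute=False)
        np.testing.assert_allclose(R[0], dense.W[:, 1].reshape(6, 3), rtol=1e-12)
        # the default saliency map is the gradient magnitude
        np.testing.assert_allclose(attr.saliency(dec, x, 1)[0], np.abs(R[0]), rtol=1e-12)

    def test_ixg_is_saliency_times_input(self, tiny_decoder, small_temporal):
        epochs, _ = small_temporal
        X, t = epochs.data[:3], epochs.labels[:3]
        ixg = attr.input_x_gradient(tiny_decoder, X, t)
        sal = attr.saliency(tiny_decoder, X, t, absolute=False)
        np.testing.assert_allclose(ixg, sal * X / tiny_decoder.scale_, rtol=1e-12, atol=1e-15)

    def test_ixg_zero_input_is_zero(self):
        dec, _ = linear_decoder()
        assert np.all(attr.input_x_gradient(dec, np.zeros((6, 3)), 0) == 0)

    def test_finite_difference_oracle(self):
        dec, _, _ = relu_toy(seed=3)
        x = np.random.default_rng(4).standard_normal((4, 3))
        R = attr.saliency(dec, x, 2, absolute=False)[0]
        eps = 1e-6
        for idx in [(0, 0), (2, 1), (3, 2)]:
            xp = x.copy(); xp[idx] += eps
            xm = x.copy(); xm[idx] -= eps
            net = dec.net_
            fd = (net.forward(xp[None, ..., None])[0, 2]
                  - net.forward(xm[None, ..., None])[0, 2]) / (2 * eps)
            assert R[idx] == pytest.approx(fd, rel=1e-4, abs=1e-10)


class TestModifiedBackprop:
    def test_rules_vacuous_without_relu(self):
        dec, _ = linear_decoder(seed=2)
        x = np.random.default_rng(0).standard_normal((6, 3))
        sal = attr.saliency(dec, x, 0, absolute=False)
        np.testing.assert_allclose(attr.deconvolution(dec, x, 0), sal, rtol=1e-12)
        np.testing.assert_allclose(attr.guided_backprop(dec, x, 0), sal, rtol=1e-12)

    def test_single_relu_mask_enumeration(self):
        dec, d1, d2 = relu_toy(seed=5)
        x = np.random.default_rng(6).standard_normal((4, 3))
        dec.net_.forward((x / dec.scale_)[None, ..., None].astype(np.float64))
        mask = dec.net_.layer("relu_h").mask[0]
        g_top = d2.W[:, 1]  # top-down signal into the ReLU
        pos = np.maximum(g_top, 0)
        deconv_expect = (pos @ d1.W.T).reshape(4, 3)
        guided_expect = ((pos * mask) @ d1.W.T).reshape(4, 3)
        np.testing.assert_allclose(attr.deconvolution(dec, x, 1)[0], deconv_expect, rtol=1e-10)
        np.testing.assert_allclose(attr.guided_backprop(dec, x, 1)[0], guided_expect, rtol=1e-10)

    def test_all_dead_relus_give_zero_guided_map(self):
        dec, _, _ = relu_toy(seed=7, bias_shift=-100.0)
        x = 0.01 * np.random.default_rng(8).standard_normal((4, 3))
        assert np.all(attr.guided_backprop(dec, x, 0) == 0)


def cam_toy(T=4, C=2, w=2.0):
    """One 1x1 positive conv filter + all-ones linear head: GradCAM == A."""
    rng = np.random.default_rng(0)
    conv = TemporalConv(1, 1, 1, rng, name="conv1", dtype=np.float64)
    conv.W[:] = w
    conv.b[:] = 0
    relu = ReLU(name="relu5")
    head = Dense(T * C, 1, rng, name="out", dtype=np.float64)
    head.W[:] = 1.0
    head.b[:] = 0
    return ToyDecoder(Network([conv, relu, Flatten(), head]), 1)


class TestCamFamily:
    def test_gradcam_identity_toy_closed_form(self):
        dec = cam_toy(w=2.0)
        x = np.abs(np.random.default_rng(1).standard_normal((4, 2))) + 0.1
        R = attr.gradcam(dec, x, 0)
        # gradient w.r.t. A is 1 everywhere -> alpha = 1, map = ReLU(A) = 2x
        np.testing.assert_allclose(R[0], 2.0 * x, rtol=1e-10)

    def test_gradcam_nonnegative_and_input_shaped(self, tiny_decoder, small_temporal):
        epochs, _ = small_temporal
        for fn in (attr.gradcam, attr.gradcam_pp, attr.layercam, attr.fullgrad):
            R = fn(tiny_decoder, epochs.data[:2], epochs.labels[:2])
            assert R.shape == (2, 250, 62)
            assert R.min() >= 0

    def test_gradcam_pp_single_filter_reduces_to_gradcam(self):
        dec = cam_toy(w=1.0)
        x = np.abs(np.random.default_rng(2).standard_normal((4, 2))) + 0.1
        gc = attr.gradcam(dec, x, 0)[0]
        gcpp = attr.gradcam_pp(dec, x, 0)[0]
        np.testing.assert_allclose(gc / gc.max(), gcpp / gcpp.max(), atol=1e-6)

    def test_guided_gradcam_is_exact_product(self, tiny_decoder, small_temporal):
        epochs, _ = small_temporal
        X, t = epochs.data[:2], epochs.labels[:2]
        prod = attr.gradcam(tiny_decoder, X, t) * attr.guided_backprop(tiny_decoder, X, t)
        np.testing.assert_array_equal(attr.guided_gradcam(tiny_decoder, X, t), prod)
        # support of the product is inside the GradCAM support
        gg = attr.guided_gradcam(tiny_decoder, X, t)
        assert np.all((gg != 0) <= (attr.gradcam(tiny_decoder, X, t) != 0))

    def test_layercam_single_layer_equals_pixelweighted_map(self):
        dec = cam_toy(w=3.0)
        x = np.abs(np.random.default_rng(3).standard_normal((4, 2))) + 0.1
        R = attr.layercam(dec, x, 0)[0]
        A = 3.0 * x  # grad is 1 everywhere -> ReLU(g) * A = A, then max-normalized
        np.testing.assert_allclose(R, A / A.max(), rtol=1e-10)

    def test_scorecam_constant_feature_map_degenerates_to_zero(self):
        rng = np.random.default_rng(0)
        conv = TemporalConv(1, 1, 1, rng, name="conv1", dtype=np.float64)
        conv.W[:] = 0.0
        conv.b[:] = 1.0  # constant positive activation
        head = Dense(8, 2, rng, name="out", dtype=np.float64)
        dec = ToyDecoder(Network([conv, ReLU(name="relu5"), Flatten(), head]), 2)
        R = attr.scorecam(dec, np.random.default_rng(1).standard_normal((4, 2)), 0)
        assert np.all(R == 0)

    def test_scorecam_weights_are_masked_softmax_scores(self, tiny_decoder, small_temporal):
        """Re-derive the filter weights by direct forward passes."""
        epochs, _ = small_temporal
        x = epochs.data[0]
        t = int(epochs.labels[0])
        R = attr.scorecam(tiny_decoder, x, t)[0]
        net = tiny_decoder.net_
        Xs = (x / tiny_decoder.scale_)[None, ..., None].astype(np.float32)
        net.forward(Xs)
        A = np.asarray(net.layer("relu5").y, dtype=np.float64)[0]
        H = attr._upsample_time(np.moveaxis(A, -1, 0), 250)
        lo = H.min(axis=(1, 2), keepdims=True)
        hi = H.max(axis=(1, 2), keepdims=True)
        rngs = np.where(hi - lo > 0, hi - lo, 1.0)
        H = np.where(hi - lo > 0, (H - lo) / rngs, 0.0)
        w = softmax(net.forward((Xs[0][None] * H[..., None]).astype(np.float32)))[:, t]
        np.testing.assert_allclose(R, np.maximum(np.einsum("k,ktc->tc", w, H), 0), atol=1e-6)


class TestFullGrad:
    def test_bias_free_net_reduces_to_abs_ixg(self):
        dec, _ = linear_decoder(seed=4)
        x = np.random.default_rng(5).standard_normal((6, 3))
        R = attr.fullgrad(dec, x, 1)[0]
        ixg = np.abs(attr.input_x_gradient(dec, x, 1)[0])
        np.testing.assert_allclose(R, (ixg - ixg.min()) / (ixg.max() - ixg.min()), rtol=1e-10)

    def test_completeness_identity(self, tiny_decoder, small_temporal):
        epochs, _ = small_temporal
        X, t = epochs.data[:5], epochs.labels[:5]
        inp, bias_terms, y_c = attr.fullgrad_decomposition(tiny_decoder, X, t)
        total = inp.sum(axis=(1, 2)) + sum(
            v.sum(axis=tuple(range(1, v.ndim))) for v in bias_terms.values())
        np.testing.assert_allclose(total, y_c, rtol=1e-5)


class TestLRP:
    def test_single_linear_layer_conservation(self):
        dec, dense = linear_decoder(seed=6)
        x = np.random.default_rng(7).standard_normal((6, 3))
        R = attr.lrp_epsilon(dec, x, 0, eps=1e-12)
        np.testing.assert_allclose(R[0], dense.W[:, 0].reshape(6, 3) * x, rtol=1e-6)
        y = dec.net_.forward(x[None, ..., None])[0, 0]
        assert R.sum() == pytest.approx(y, rel=1e-6)

    def test_conservation_leakage_small_on_biasfree_relu_net(self):
        dec, d1, d2 = relu_toy(seed=9)
        d1.b[:] = 0
        d2.b[:] = 0
        x = np.random.default_rng(10).standard_normal((4, 3))
        R = attr.lrp_epsilon(dec, x, 1)
        y = dec.net_.forward(x[None, ..., None])[0, 1]
        assert abs(R.sum() - y) <= 0.01 * abs(y)

    def test_matches_ixg_on_trained_relu_decoder(self, tiny_decoder, small_temporal):
        """With only ReLU non-linearities the epsilon rule approximates IxG."""
        epochs, _ = small_temporal
        X, t = epochs.data[:8], epochs.labels[:8]
        lrp = attr.lrp_epsilon(tiny_decoder, X, t).ravel()
        ixg = attr.input_x_gradient(tiny_decoder, X, t).ravel()
        assert np.corrcoef(lrp, ixg)[0, 1] >= 0.99


class TestDeepLift:
    def test_linear_net_zero_baseline_closed_form(self):
        dec, dense = linear_decoder(seed=8)
        x = np.random.default_rng(9).standard_normal((6, 3))
        R = attr.deeplift(dec, x, 1)
        np.testing.assert_allclose(R[0], dense.W[:, 1].reshape(6, 3) * x, rtol=1e-10)

    def test_baseline_input_attributes_nothing(self):
        dec, _, _ = relu_toy(seed=11)
        assert np.all(attr.deeplift(dec, np.zeros((4, 3)), 0) == 0)

    def test_summation_to_delta_on_trained_decoder(self, tiny_decoder, small_temporal):
        epochs, _ = small_temporal
        X, t = epochs.data[:10], epochs.labels[:10]
        R = attr.deeplift(tiny_decoder, X, t)
        net, Xs, tt = attr._prep(tiny_decoder, X, t)
        y_x = net.forward(Xs)[np.arange(10), tt]
        y_0 = net.forward(np.zeros((1, 250, 62, 1)))[0][tt]
        np.testing.assert_allclose(R.sum(axis=(1, 2)), y_x - y_0, rtol=1e-4)


class TestDispatcher:
    def test_routes_and_matches_direct_call(self, tiny_decoder, small_temporal):
        epochs, _ = small_temporal
        X, t = epochs.data[:2], epochs.labels[:2]
        np.testing.assert_array_equal(
            attr.attribute(tiny_decoder, X, t, "saliency"), attr.saliency(tiny_decoder, X, t))

    def test_all_methods_return_input_grid(self, tiny_decoder, small_temporal):
        epochs, _ = small_temporal
        X, t = epochs.data[:2], epochs.labels[:2]
        for method in attr.METHODS:
            R = attr.attribute(tiny_decoder, X, t, method)
            assert R.shape == (2, 250, 62), method
            assert np.isfinite(R).all(), method

    def test_unknown_method_rejected(self, tiny_decoder):
        with pytest.raises(KeyError):
            attr.attribute(tiny_decoder, np.zeros((1, 250, 62)), 0, "shapley")

    def test_deterministic(self, tiny_decoder, small_temporal):
        epochs, _ = small_temporal
        X, t = epochs.data[:2], epochs.labels[:2]
        a = attr.attribute(tiny_decoder, X, t, "deeplift")
        b = attr.attribute(tiny_decoder, X, t, "deeplift")
        np.testing.assert_array_equal(a, b)


class TestReduceToChannels:
    def test_single_channel_map_is_one_hot(self):
        m = np.zeros((250, 62))
        m[:, 17] = 1.0
        v = attr.reduce_to_channels(m)
        assert v[17] == 1.0 and v.sum() == 1.0

    def test_scale_invariant(self):
        m = np.random.default_rng(0).standard_normal((250, 62))
        np.testing.assert_allclose(attr.reduce_to_channels(2 * m), attr.reduce_to_channels(m))

    def test_ground_truth_relevance_stays_lateralized(self, small_temporal, montage):
        _, gt = small_temporal
        v = attr.reduce_to_channels(gt.relevance[0])
        assert v.max() == 1.0 and v.min() >= 0
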