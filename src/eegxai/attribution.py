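"""Twelve backpropagation-based attribution methods on the input grid.

Every method takes a trained :class:`~eegxai.decoder.EEGDecoder` and a
batch of raw epochs (uV, shape ``(B, 250, 62)``) with per-trial target
classes, and returns relevance maps of the same shape.  The class score
that is differentiated is the pre-softmax logit of the target class (the
softmax saturates and would null gradients).

Gradient-family methods (saliency, input x gradient, deconvolution, guided
backpropagation, LRP-epsilon, DeepLift, FullGrad) run a custom backward
pass through the network.  CAM-family methods (GradCAM, GradCAM++,
LayerCAM, ScoreCAM, and guided GradCAM) read feature maps from the last
temporal convolution — the deepest layer that still resolves the 62
electrode channels — and are upsampled bilinearly along the time axis
only, since the channel axis carries no spatial order.

Sign conventions: input x gradient, deconvolution, guided backpropagation,
LRP and DeepLift are signed; the CAM family and FullGrad are non-negative
by construction, and saliency follows the standard convention of
returning the gradient magnitude.
"""
from __future__ import annotations

import numpy as np

from ._nn import (
    Dense,
    Dropout,
    Flatten,
    MaxPoolTime,
    Network,
    ReLU,
    SpatialConv,
    TemporalConv,
    softmax,
)
from .decoder import EEGDecoder

__all__ = [
    "METHODS",
    "SIGNED_METHODS",
    "attribute",
    "saliency",
    "input_x_gradient",
    "deconvolution",
    "guided_backprop",
    "gradcam",
    "gradcam_pp",
    "guided_gradcam",
    "layercam",
    "scorecam",
    "fullgrad",
    "fullgrad_decomposition",
    "lrp_epsilon",
    "deeplift",
    "reduce_to_channels",
]

#: default CAM target: ReLU output of the last temporal convolution
CAM_LAYER = "relu5"

SIGNED_METHODS = frozenset(
    {"deconv", "guided_bp", "ixg", "lrp_eps", "deeplift"}
)


# ---------------------------------------------------------------------------
# plumbing

def _prep(decoder: EEGDecoder, X: np.ndarray, targets) -> tuple[Network, np.ndarray, np.ndarray]:
    """Float64 copy of the trained net plus scaled 4-D inputs and targets."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 2:
        X = X[None]
    B = X.shape[0]
    targets = np.broadcast_to(np.asarray(targets, dtype=int), (B,)).copy()
    n_classes = decoder.spec_.n_classes
    if (targets < 0).any() or (targets >= n_classes).any():
        raise ValueError("target class out of range")
    net = getattr(decoder, "_net64_cache", None)
    if net is None:
        net = decoder.net_.astype(np.float64)
        decoder._net64_cache = net
    Xs = (X / decoder.scale_)[..., None]
    return net, Xs, targets


def _onehot_grad(logits: np.ndarray, targets: np.ndarray) -> np.ndarray:
    g = np.zeros_like(logits)
    g[np.arange(logits.shape[0]), targets] = 1.0
    return g


def _input_gradient(net: Network, Xs: np.ndarray, targets: np.ndarray,
                    mode: str = "plain") -> np.ndarray:
    logits = net.forward(Xs)
    return net.backward(_onehot_grad(logits, targets), mode=mode)[..., 0]


def _upsample_matrix(m: int, out_len: int, dtype=np.float64) -> np.ndarray:
    """Linear-interpolation operator (out_len x m), endpoints aligned."""
    if m == 1:
        return np.ones((out_len, 1), dtype=dtype)
    src = np.linspace(0.0, m - 1.0, out_len)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, m - 1)
    w = src - lo
    U = np.zeros((out_len, m), dtype=dtype)
    U[np.arange(out_len), lo] += 1.0 - w
    U[np.arange(out_len), hi] += w
    return U


def _upsample_time(maps: np.ndarray, out_len: int) -> np.ndarray:
    """Bilinear upsampling of (..., m, C) feature maps along the time axis."""
    m = maps.shape[-2]
    U = _upsample_matrix(m, out_len, maps.dtype)
    return np.einsum("tm,...mc->...tc", U, maps)


# ---------------------------------------------------------------------------
# gradient family

def saliency(decoder: EEGDecoder, X, targets, absolute: bool = True) -> np.ndarray:
    """Saliency map: magnitude of the class-logit gradient w.r.t. the input.

    The conventional saliency map (and the default of standard attribution
    tooling) is the absolute gradient; pass ``absolute=False`` for the raw
    signed gradient ``dS_c/dx``.
    """
    net, Xs, t = _prep(decoder, X, targets)
    g = _input_gradient(net, Xs, t)
    return np.abs(g) if absolute else g


def input_x_gradient(decoder: EEGDecoder, X, targets) -> np.ndarray:
    """Gradient times (scaled) input."""
    net, Xs, t = _prep(decoder, X, targets)
    return _input_gradient(net, Xs, t) * Xs[..., 0]


def deconvolution(decoder: EEGDecoder, X, targets) -> np.ndarray:
    """Backward pass where ReLUs pass only positive top-down signal."""
    net, Xs, t = _prep(decoder, X, targets)
    return _input_gradient(net, Xs, t, mode="deconv")


def guided_backprop(decoder: EEGDecoder, X, targets) -> np.ndarray:
    """Backward pass keeping only positive gradients at active ReLUs."""
    net, Xs, t = _prep(decoder, X, targets)
    return _input_gradient(net, Xs, t, mode="guided")


# ---------------------------------------------------------------------------
# CAM family

def _cam_forward_backward(net: Network, Xs: np.ndarray, targets: np.ndarray,
                          layer_name: str) -> tuple[np.ndarray, np.ndarray]:
    """Activations A and gradients dy_c/dA of the CAM target layer.

    Both have shape (B, m, C, K).
    """
    logits = net.forward(Xs)
    net.backward(_onehot_grad(logits, targets))
    layer = net.layer(layer_name)
    return np.array(layer.y, copy=True), np.array(layer.grad_out, copy=True)


def gradcam(decoder: EEGDecoder, X, targets, layer: str = CAM_LAYER) -> np.ndarray:
    """Feature maps weighted by spatially averaged logit gradients, ReLU'd.

    ``alpha_k = mean_ij dy_c/dA_kij``, ``map = ReLU(sum_k alpha_k A_k)``,
    upsampled to the input grid.
    """
    net, Xs, t = _prep(decoder, X, targets)
    A, G = _cam_forward_backward(net, Xs, t, layer)
    alpha = G.mean(axis=(1, 2), keepdims=True)  # (B,1,1,K)
    cam = np.maximum((alpha * A).sum(axis=-1), 0.0)  # (B,m,C)
    return _upsample_time(cam, Xs.shape[1])


def gradcam_pp(decoder: EEGDecoder, X, targets, layer: str = CAM_LAYER) -> np.ndarray:
    """GradCAM++ closed-form pixel weights (exponential-score formulation).

    ``alpha_ij = g_ij^2 / (2 g_ij^2 + sum_ab A_ab g_ab^3)`` per filter,
    ``w_k = sum_ij alpha_ij ReLU(g_ij)``, combined and ReLU'd as GradCAM.
    """
    net, Xs, t = _prep(decoder, X, targets)
    A, G = _cam_forward_backward(net, Xs, t, layer)
    g2 = G * G
    g3 = g2 * G
    denom = 2.0 * g2 + (A * g3).sum(axis=(1, 2), keepdims=True)
    safe = np.abs(denom) > 1e-12
    alpha = np.where(safe, g2 / np.where(safe, denom, 1.0), 0.0)
    w = (alpha * np.maximum(G, 0.0)).sum(axis=(1, 2), keepdims=True)  # (B,1,1,K)
    cam = np.maximum((w * A).sum(axis=-1), 0.0)
    return _upsample_time(cam, Xs.shape[1])


def guided_gradcam(decoder: EEGDecoder, X, targets, layer: str = CAM_LAYER) -> np.ndarray:
    """Elementwise product of GradCAM and guided backpropagation."""
    return gradcam(decoder, X, targets, layer) * guided_backprop(decoder, X, targets)


def layercam(decoder: EEGDecoder, X, targets) -> np.ndarray:
    """LayerCAM over all five temporal convolutions.

    Per layer, ``ReLU(sum_k ReLU(g) * A)`` is upsampled to the input grid
    and max-normalized; the layer maps are then averaged.
    """
    net, Xs, t = _prep(decoder, X, targets)
    logits = net.forward(Xs)
    net.backward(_onehot_grad(logits, t))
    out_len = Xs.shape[1]
    acc = np.zeros((Xs.shape[0], out_len, Xs.shape[2]))
    n = 0
    for l in net.layers:
        if isinstance(l, ReLU) and l.name.startswith("relu"):
            A, G = l.y, l.grad_out
            m = np.maximum((np.maximum(G, 0.0) * A).sum(axis=-1), 0.0)
            m = _upsample_time(m, out_len)
            peak = m.max(axis=(1, 2), keepdims=True)
            np.divide(m, peak, out=m, where=peak > 0)
            acc += m
            n += 1
    return acc / max(n, 1)


def scorecam(decoder: EEGDecoder, X, targets, layer: str = CAM_LAYER) -> np.ndarray:
    """Forward-pass CAM: feature maps as input masks, softmax scores as weights.

    Each of the K feature maps is upsampled to the input grid, min-max
    normalized to [0, 1] (constant maps degenerate to a zero mask), used to
    mask the input, and scored by a forward pass; the softmax score of the
    target class weights the mask in the final non-negative combination.
    """
    _, Xs, t = _prep(decoder, X, targets)
    # score weights come from forward passes only; float32 suffices and
    # the masked-input batches dominate the cost
    net = decoder.net_
    Xs = Xs.astype(np.float32)
    B, T = Xs.shape[0], Xs.shape[1]
    net.forward(Xs)
    A = np.array(net.layer(layer).y, dtype=np.float64)  # (B,m,C,K)
    K = A.shape[-1]
    out = np.zeros((B, T, Xs.shape[2]))
    for i in range(B):
        Hi = _upsample_time(np.moveaxis(A[i], -1, 0), T)  # (K,T,C)
        lo = Hi.min(axis=(1, 2), keepdims=True)
        hi = Hi.max(axis=(1, 2), keepdims=True)
        rng = hi - lo
        H = np.where(rng > 0, (Hi - lo) / np.where(rng == 0, 1.0, rng), 0.0)
        masked = (Xs[i][None] * H[..., None]).astype(np.float32)  # (K,T,C,1)
        logits = net.forward(masked)
        w = softmax(logits)[:, t[i]]  # (K,)
        out[i] = np.maximum(np.einsum("k,ktc->tc", w, H), 0.0)
    return out


# ---------------------------------------------------------------------------
# FullGrad

def fullgrad_decomposition(decoder: EEGDecoder, X, targets):
    """Exact decomposition ``y_c = grad_x . x + sum_layers grad_b . b``.

    Returns the signed input-gradient term ``(B, 250, 62)``, a dict of
    per-layer signed bias-gradient maps (summed over filters, at native
    resolution), and the logits — the completeness identity of FullGrad
    for ReLU/max-pool networks.
    """
    net, Xs, t = _prep(decoder, X, targets)
    logits = net.forward(Xs)
    dx = net.backward(_onehot_grad(logits, t))
    input_term = dx[..., 0] * Xs[..., 0]
    bias_terms = {}
    for l in net.layers:
        if l.has_bias:
            g = l.grad_out  # grad w.r.t. pre-activation output
            bias_terms[l.name] = g * l.b  # broadcast over trailing filter axis
    return input_term, bias_terms, logits[np.arange(Xs.shape[0]), t]


def fullgrad(decoder: EEGDecoder, X, targets) -> np.ndarray:
    """Aggregate of absolute input-gradient and bias-gradient components.

    Each component is taken in absolute value, upsampled to the input grid
    and min-max normalized before summation; spatially constant components
    (dense-layer biases) normalize to zero and drop out.
    """
    input_term, bias_terms, _ = fullgrad_decomposition(decoder, X, targets)
    B, T, C = input_term.shape

    def _norm(m):
        lo = m.min(axis=(1, 2), keepdims=True)
        hi = m.max(axis=(1, 2), keepdims=True)
        rng = hi - lo
        return np.where(rng > 0, (m - lo) / np.where(rng == 0, 1.0, rng), 0.0)

    out = _norm(np.abs(input_term))
    for name, term in bias_terms.items():
        if term.ndim != 4:  # dense biases: no spatial extent
            continue
        m = np.abs(term).sum(axis=-1)  # (B, m, c)
        m = _upsample_time(m, T)
        if m.shape[2] == 1:  # post-spatial-conv maps: broadcast channels
            m = np.broadcast_to(m, (B, T, C)).copy()
        out = out + _norm(m)
    return out


# ---------------------------------------------------------------------------
# LRP (epsilon rule)

def lrp_epsilon(decoder: EEGDecoder, X, targets, eps: float = 1e-6) -> np.ndarray:
    """Layer-wise relevance propagation with the epsilon stabilizer.

    The class logit is redistributed layer by layer under the conservation
    principle: for linear layers ``R_j = sum_k a_j w_jk / (z_k +
    eps*sign(z_k)) R_k``; max-pooling routes relevance through the argmax
    switch; ReLU/dropout/flatten pass relevance unchanged.
    """
    net, Xs, t = _prep(decoder, X, targets)
    logits = net.forward(Xs)
    B = Xs.shape[0]
    R = np.zeros_like(logits)
    R[np.arange(B), t] = logits[np.arange(B), t]

    def stabilized(z):
        return z + eps * np.where(z >= 0, 1.0, -1.0)

    for l in reversed(net.layers):
        if isinstance(l, (Dense, TemporalConv, SpatialConv)):
            s = R / stabilized(l.y)
            R = l.x * l.backprop_linear(s)
        elif isinstance(l, MaxPoolTime):
            R = l.backward(R)
        elif isinstance(l, (ReLU, Dropout)):
            pass
        elif isinstance(l, Flatten):
            R = R.reshape(l.in_shape)
        else:  # pragma: no cover
            raise TypeError(f"LRP rule missing for layer {type(l).__name__}")
    return R[..., 0]


# ---------------------------------------------------------------------------
# DeepLift (rescale rule, zero reference)

def deeplift(decoder: EEGDecoder, X, targets) -> np.ndarray:
    """DeepLift rescale rule against an all-zero reference input.

    Multipliers are propagated from the logit to the input: linear layers
    pass them through the transposed weights; ReLUs rescale by
    ``delta_out/delta_in`` (gradient fallback where ``delta_in`` vanishes);
    max-pooling routes the multiplier to the in-window position with the
    largest ``|delta_in|``, which preserves summation-to-delta exactly.
    The attribution is ``multiplier * (x - 0)``.
    """
    net, Xs, t = _prep(decoder, X, targets)
    B = Xs.shape[0]
    # reference activations (input-independent; reference input is zero)
    x0 = np.zeros((1,) + Xs.shape[1:])
    ref: dict[str, dict[str, np.ndarray]] = {}
    h = x0
    for l in net.layers:
        entry = {"x": h}
        h = l.forward(h)
        entry["y"] = h
        ref[l.name] = entry
    # actual forward (re-populates caches)
    logits = net.forward(Xs)
    m = _onehot_grad(logits, t)
    for l in reversed(net.layers):
        r = ref[l.name]
        if isinstance(l, (Dense, TemporalConv, SpatialConv)):
            m = l.backprop_linear(m)
        elif isinstance(l, ReLU):
            # pre-activation deltas: input of this ReLU vs reference input
            delta_in = l.x - r["x"]
            delta_out = l.y - r["y"]
            safe = np.abs(delta_in) > 1e-10
            ratio = np.where(safe, delta_out / np.where(safe, delta_in, 1.0), l.mask)
            m = m * ratio
        elif isinstance(l, MaxPoolTime):
            m = _deeplift_pool(l, r, m)
        elif isinstance(l, Dropout):
            pass
        elif isinstance(l, Flatten):
            m = m.reshape(l.in_shape)
        else:  # pragma: no cover
            raise TypeError(f"DeepLift rule missing for layer {type(l).__name__}")
    return (m * Xs)[..., 0]


def _deeplift_pool(l: MaxPoolTime, r: dict, m: np.ndarray) -> np.ndarray:
    x = l.x
    x0 = r["x"]
    B, T, C, I = x.shape
    To = T // 2
    d0 = x[:, 0:2 * To:2] - x0[:, 0:2 * To:2]
    d1 = x[:, 1:2 * To:2] - x0[:, 1:2 * To:2]
    y = np.where(l.first, x[:, 0:2 * To:2], x[:, 1:2 * To:2])
    y0 = np.maximum(x0[:, 0:2 * To:2], x0[:, 1:2 * To:2])
    delta_out = y - y0
    pick0 = np.abs(d0) >= np.abs(d1)
    dsel = np.where(pick0, d0, d1)
    safe = np.abs(dsel) > 1e-12
    mul = np.where(safe, delta_out / np.where(safe, dsel, 1.0), 0.0) * m
    out = np.zeros(x.shape, dtype=m.dtype)
    paired = out[:, :2 * To].reshape(B, To, 2, C, I)
    np.multiply(mul, pick0, out=paired[:, :, 0])
    np.multiply(mul, ~pick0, out=paired[:, :, 1])
    return out


# ---------------------------------------------------------------------------
# dispatcher & reductions

METHODS = {
    "saliency": saliency,
    "deconv": deconvolution,
    "guided_bp": guided_backprop,
    "ixg": input_x_gradient,
    "gradcam": gradcam,
    "gradcam_pp": gradcam_pp,
    "guided_gradcam": guided_gradcam,
    "layercam": layercam,
    "scorecam": scorecam,
    "fullgrad": fullgrad,
    "lrp_eps": lrp_epsilon,
    "deeplift": deeplift,
}


def attribute(decoder: EEGDecoder, X, targets, method: str,
              batch_size: int = 8) -> np.ndarray:
    """Compute relevance maps for one method, batched over trials.

    Deterministic given the decoder weights and inputs.  Returns
    ``(B, 250, 62)`` float maps on the input grid.
    """
    if method not in METHODS:
        raise KeyError(f"unknown attribution method {method!r}; "
                       f"choose from {sorted(METHODS)}")
    fn = METHODS[method]
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 2:
        X = X[None]
    targets = np.broadcast_to(np.asarray(targets, dtype=int), (X.shape[0],))
    out = []
    for lo in range(0, X.shape[0], batch_size):
        out.append(fn(decoder, X[lo:lo + batch_size], targets[lo:lo + batch_size]))
    # release the cached activations/workspaces of the attribution passes
    net64 = getattr(decoder, "_net64_cache", None)
    if net64 is not None:
        net64.clear_caches()
    decoder.net_.clear_caches()
    return np.concatenate(out, axis=0)


def reduce_to_channels(maps: np.ndarray) -> np.ndarray:
    """Collapse (…, 250, 62) maps to max-normalized 62-channel vectors.

    ``v_c = sum_t |R[t, c]|``, then divided by its maximum (all-zero maps
    stay zero).  Used to compare attribution topographies against the
    ground-truth channel vector in the spatial condition.
    """
    v = np.abs(maps).sum(axis=-2)
    peak = v.max(axis=-1, keepdims=True)
    return np.divide(v, peak, out=np.zeros_like(v), where=peak > 0)
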