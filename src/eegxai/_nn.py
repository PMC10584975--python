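"""Minimal CNN engine for multichannel time series.

Self-contained numpy implementation of the forward pass, backpropagation
and Adam training used by the EEG decoder.  Keeping the engine in-package
gives the attribution module direct access to everything the explanation
methods need: cached activations at every layer, gradients with respect to
any intermediate tensor, and modified ReLU backward rules (deconvolution /
guided backpropagation) that framework autodiff does not expose.

Tensor layout is ``(batch, time, channel, filters)`` throughout; the raw
input enters with a single filter axis, ``(B, 250, 62, 1)``.

Backward ``mode``:
  * ``"plain"``  - exact gradient (used for training and gradient-based maps)
  * ``"deconv"`` - ReLUs pass only positive top-down signal, ignoring the
    forward activation mask
  * ``"guided"`` - ReLUs pass signal only where both the forward activation
    and the top-down signal are positive

During any backward traversal each layer records the gradient w.r.t. its
output in ``layer.grad_out`` (used by CAM-family and FullGrad methods).
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "TemporalConv",
    "SpatialConv",
    "ReLU",
    "MaxPoolTime",
    "Flatten",
    "Dense",
    "Dropout",
    "Network",
    "Adam",
    "softmax",
    "cross_entropy",
]

# im2col scratch buffers are chunked to stay below this many bytes
_CHUNK_BYTES = 96 * 2**20


class Layer:
    """Base class; subclasses cache what their backward rules need."""

    name: str = ""
    has_bias: bool = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray, mode: str = "plain", accumulate: bool = False) -> np.ndarray:
        raise NotImplementedError

    def param_names(self) -> tuple[str, ...]:
        return ()


class TemporalConv(Layer):
    """Valid convolution along the time axis, independent per EEG channel.

    Weights ``W`` have shape (kernel, in_filters, out_filters).
    """

    has_bias = True

    def __init__(self, in_filters: int, out_filters: int, kernel: int, rng: np.random.Generator,
                 name: str = "conv", dtype=np.float32):
        self.k = int(kernel)
        fan_in = self.k * in_filters
        std = np.sqrt(2.0 / fan_in)
        self.W = (rng.standard_normal((self.k, in_filters, out_filters)) * std).astype(dtype)
        self.b = np.zeros(out_filters, dtype=dtype)
        self.name = name
        self.dW = None
        self.db = None
        self.x = None
        self.y = None
        self.grad_out = None

    def param_names(self):
        return ("W", "b")

    def _buf(self, key: str, shape, dtype) -> np.ndarray:
        # persistent scratch buffers: repeated fresh allocation of the large
        # im2col workspaces costs more than the GEMMs themselves
        store = self.__dict__.setdefault("_scratch", {})
        buf = store.get(key)
        if buf is None or buf.shape != shape or buf.dtype != dtype:
            buf = np.empty(shape, dtype=dtype)
            store[key] = buf
        return buf

    def _im2col(self, key: str, x: np.ndarray, k: int) -> np.ndarray:
        """(B, T, C, I) -> contiguous (B, To, C, k*I) window buffer."""
        B, T, C, I = x.shape
        To = T - k + 1
        buf = self._buf(key, (B, To, C, k, I), x.dtype)
        for dt in range(k):
            buf[:, :, :, dt, :] = x[:, dt:dt + To]
        return buf.reshape(B, To, C, k * I)

    def forward(self, x, train=False):
        B, T, C, I = x.shape
        k = self.k
        To = T - k + 1
        O = self.W.shape[2]
        self.col = self._im2col("col", x, k)
        y = self.col @ self.W.reshape(k * I, O)
        y += self.b
        self.x, self.y = x, y
        return y

    def backward(self, g, mode="plain", accumulate=False, compute_dx=True):
        x = self.x
        B, T, C, I = x.shape
        k = self.k
        To = T - k + 1
        O = self.W.shape[2]
        if accumulate:
            col = self.col.reshape(-1, k * I)
            self.dW = (col.T @ g.reshape(-1, O)).reshape(self.W.shape).astype(self.W.dtype)
            self.db = g.sum(axis=(0, 1, 2), dtype=np.float64).astype(self.b.dtype)
        if not compute_dx:
            return None
        # gradient w.r.t. input = full correlation with the flipped kernel,
        # computed as a second im2col GEMM over the zero-padded upstream grad
        gpad = self._buf("gpad", (B, To + 2 * (k - 1), C, O), g.dtype)
        gpad[:, :k - 1] = 0
        gpad[:, k - 1:k - 1 + To] = g
        gpad[:, k - 1 + To:] = 0
        Wback = self.W[::-1].transpose(0, 2, 1).reshape(k * O, I)  # [j, o, i]
        return self._im2col("colb", gpad, k) @ Wback

    def backprop_linear(self, g):
        """Input-space image of ``g`` under the transposed convolution
        (gradient w.r.t. input, no parameter gradients)."""
        return self.backward(g, accumulate=False)


class SpatialConv(Layer):
    """Convolution spanning all EEG channels at each time point.

    Weights ``W`` have shape (channels, in_filters, out_filters); output
    collapses the channel axis to length 1.
    """

    has_bias = True

    def __init__(self, n_channels: int, in_filters: int, out_filters: int,
                 rng: np.random.Generator, name: str = "sconv", dtype=np.float32):
        fan_in = n_channels * in_filters
        std = np.sqrt(2.0 / fan_in)
        self.W = (rng.standard_normal((n_channels, in_filters, out_filters)) * std).astype(dtype)
        self.b = np.zeros(out_filters, dtype=dtype)
        self.name = name
        self.dW = None
        self.db = None
        self.x = None
        self.y = None
        self.grad_out = None

    def param_names(self):
        return ("W", "b")

    def forward(self, x, train=False):
        B, T, C, I = x.shape
        O = self.W.shape[2]
        Wmat = self.W.reshape(C * I, O)
        y = (x.reshape(B * T, C * I) @ Wmat).reshape(B, T, 1, O) + self.b
        self.x, self.y = x, y
        return y

    def backward(self, g, mode="plain", accumulate=False):
        x = self.x
        B, T, C, I = x.shape
        O = self.W.shape[2]
        Wmat = self.W.reshape(C * I, O)
        gm = g.reshape(B * T, O)
        if accumulate:
            self.dW = (x.reshape(B * T, C * I).T @ gm).reshape(self.W.shape).astype(self.W.dtype)
            self.db = gm.sum(axis=0, dtype=np.float64).astype(self.b.dtype)
        return (gm @ Wmat.T).reshape(B, T, C, I)

    backprop_linear = backward


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name
        self.mask = None
        self.x = None  # reference to the pre-activation input (no copy)
        self.y = None
        self.grad_out = None

    def forward(self, x, train=False):
        self.x = x
        self.mask = x > 0
        self.y = np.maximum(x, 0)
        return self.y

    def backward(self, g, mode="plain", accumulate=False):
        if mode == "plain":
            return g * self.mask
        if mode == "deconv":
            return np.maximum(g, 0)
        if mode == "guided":
            return g * (self.mask & (g > 0))
        raise ValueError(f"unknown backward mode {mode!r}")


class MaxPoolTime(Layer):
    """2x1 max pooling over time, stride 2 (floor division on odd lengths)."""

    def __init__(self, name: str = "pool"):
        self.name = name
        self.first = None  # True where the earlier sample of a pair wins
        self.in_shape = None
        self.x = None
        self.grad_out = None

    def forward(self, x, train=False):
        B, T, C, I = x.shape
        To = T // 2
        x0 = x[:, 0:2 * To:2]
        x1 = x[:, 1:2 * To:2]
        self.first = x0 >= x1
        self.in_shape = x.shape
        self.x = x
        return np.where(self.first, x0, x1)

    def backward(self, g, mode="plain", accumulate=False):
        B, T, C, I = self.in_shape
        To = T // 2
        dx = np.zeros(self.in_shape, dtype=g.dtype)
        paired = dx[:, :2 * To].reshape(B, To, 2, C, I)
        np.multiply(g, self.first, out=paired[:, :, 0])
        np.multiply(g, ~self.first, out=paired[:, :, 1])
        return dx


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        self.name = name
        self.in_shape = None
        self.grad_out = None

    def forward(self, x, train=False):
        self.in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g, mode="plain", accumulate=False):
        return g.reshape(self.in_shape)


class Dense(Layer):
    has_bias = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 name: str = "dense", dtype=np.float32, init: str = "he"):
        if init == "he":
            std = np.sqrt(2.0 / n_in)
            self.W = (rng.standard_normal((n_in, n_out)) * std).astype(dtype)
        else:  # xavier uniform, used for the linear output layer
            lim = np.sqrt(6.0 / (n_in + n_out))
            self.W = rng.uniform(-lim, lim, (n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.name = name
        self.dW = None
        self.db = None
        self.x = None
        self.y = None
        self.grad_out = None

    def param_names(self):
        return ("W", "b")

    def forward(self, x, train=False):
        self.x = x
        self.y = x @ self.W + self.b
        return self.y

    def backward(self, g, mode="plain", accumulate=False):
        if accumulate:
            self.dW = (self.x.T @ g).astype(self.W.dtype)
            self.db = g.sum(axis=0, dtype=np.float64).astype(self.b.dtype)
        return g @ self.W.T

    backprop_linear = backward


class Dropout(Layer):
    """Inverted dropout; identity at inference ("all units retained")."""

    def __init__(self, p: float, rng: np.random.Generator, name: str = "dropout"):
        self.p = float(p)
        self.rng = rng
        self.name = name
        self.dropmask = None
        self.training = False
        self.grad_out = None

    def forward(self, x, train=False):
        self.training = train
        if not train or self.p == 0:
            self.dropmask = None
            return x
        keep = self.rng.random(x.shape) >= self.p
        self.dropmask = keep.astype(x.dtype) / (1.0 - self.p)
        return x * self.dropmask

    def backward(self, g, mode="plain", accumulate=False):
        if self.dropmask is None:
            return g
        return g * self.dropmask


class Network:
    """A plain layer stack with cached activations."""

    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")

    def layer(self, name: str) -> Layer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, g: np.ndarray, mode: str = "plain", accumulate: bool = False,
                 need_input_grad: bool = True) -> np.ndarray | None:
        for i in range(len(self.layers) - 1, -1, -1):
            l = self.layers[i]
            l.grad_out = g
            if i == 0 and not need_input_grad and isinstance(l, TemporalConv):
                return l.backward(g, mode=mode, accumulate=accumulate, compute_dx=False)
            g = l.backward(g, mode=mode, accumulate=accumulate)
        return g

    def clear_caches(self) -> None:
        """Release cached activations and scratch workspaces."""
        for l in self.layers:
            for attr in ("x", "y", "mask", "first", "dropmask", "grad_out", "dW", "db", "col"):
                if hasattr(l, attr):
                    setattr(l, attr, None)
            l.__dict__.pop("_scratch", None)

    # -- parameter access -------------------------------------------------
    def parameters(self):
        out = []
        for l in self.layers:
            for pname in l.param_names():
                out.append((l, pname))
        return out

    def get_weights(self) -> dict[str, np.ndarray]:
        return {f"{l.name}.{p}": getattr(l, p).copy() for l, p in self.parameters()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for l, p in self.parameters():
            key = f"{l.name}.{p}"
            cur = getattr(l, p)
            setattr(l, p, np.asarray(weights[key], dtype=cur.dtype).reshape(cur.shape))

    def astype(self, dtype) -> "Network":
        """A structural copy of the network with weights cast to ``dtype``."""
        import copy

        clone = copy.copy(self)
        clone.layers = []
        for l in self.layers:
            lc = copy.copy(l)
            for p in l.param_names():
                setattr(lc, p, getattr(l, p).astype(dtype))
            # drop caches; scratch workspaces must not be shared across clones
            for attr in ("x", "y", "mask", "first", "dropmask", "grad_out", "dW", "db", "col"):
                if hasattr(lc, attr):
                    setattr(lc, attr, None)
            lc.__dict__.pop("_scratch", None)
            clone.layers.append(lc)
        return clone


class Adam:
    def __init__(self, net: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {}
        self.v = {}
        for l, p in net.parameters():
            key = f"{l.name}.{p}"
            self.m[key] = np.zeros_like(getattr(l, p), dtype=np.float32)
            self.v[key] = np.zeros_like(getattr(l, p), dtype=np.float32)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for l, p in self.net.parameters():
            key = f"{l.name}.{p}"
            g = getattr(l, "d" + p)
            m = self.m[key]
            v = self.v[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (self.lr / bias1) * m / (np.sqrt(v / bias2) + self.eps)
            getattr(l, p).__isub__(update)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    B = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(np.maximum(p[np.arange(B), y], 1e-300)).mean()
    g = p
    g[np.arange(B), y] -= 1.0
    g /= B
    return float(loss), g.astype(logits.dtype)
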