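"""CNN decoder for simulated scalp EEG, with randomization controls.

The architecture is a generic EEG CNN: five temporal convolutions (5x1,
stride 1, 32 filters) with 2x1/stride-2 max pooling after the first four,
one spatial convolution spanning all 62 channels, then a 32-unit dense
layer, dropout 0.5, and a softmax output.  All hidden activations are
ReLU; convolutions are unpadded.  The temporal receptive field of the last
convolutional block is 140 samples (> 125, i.e. more than half the 250 Hz
sampling rate).

:class:`EEGDecoder` is a scikit-learn estimator (``fit`` / ``predict`` /
``predict_proba``); :func:`cross_validate` runs the stratified 5-fold
protocol, and :func:`retrain_with_permuted_labels` /
:func:`reinitialize_weights` produce the label- and weight-randomized
control models used by the explanation sanity checks.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from ._nn import (
    Adam,
    Dense,
    Dropout,
    Flatten,
    MaxPoolTime,
    Network,
    ReLU,
    SpatialConv,
    TemporalConv,
    cross_entropy,
    softmax,
)

__all__ = [
    "ArchitectureSpec",
    "FoldResult",
    "receptive_field",
    "build_network",
    "EEGDecoder",
    "cross_validate",
    "retrain_with_permuted_labels",
    "reinitialize_weights",
]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyperparameters of the decoder CNN."""

    n_temporal_conv: int = 5
    filters: int = 32
    temporal_kernel: int = 5
    pool: int = 2
    n_pooled_blocks: int = 4  # pooling after temporal convs 1..4
    n_channels: int = 62
    n_samples: int = 250
    dense_units: int = 32
    dropout: float = 0.5
    n_classes: int = 4

    def temporal_layer_stack(self) -> list[tuple[int, int]]:
        """(kernel, stride) sequence along the time axis."""
        stack: list[tuple[int, int]] = []
        for i in range(self.n_temporal_conv):
            stack.append((self.temporal_kernel, 1))
            if i < self.n_pooled_blocks:
                stack.append((self.pool, self.pool))
        return stack

    def temporal_output_length(self) -> int:
        n = self.n_samples
        for k, s in self.temporal_layer_stack():
            n = (n - k) // s + 1
        return n

    def flatten_size(self) -> int:
        return self.temporal_output_length() * 1 * self.filters


def receptive_field(spec: ArchitectureSpec) -> int:
    """Temporal receptive field (in samples) of the final convolutional block.

    Standard recursion: ``RF = 1 + sum_i (k_i - 1) * prod_{j<i} s_j``.
    """
    rf = 1
    jump = 1
    for k, s in spec.temporal_layer_stack():
        rf += (k - 1) * jump
        jump *= s
    return rf


def build_network(spec: ArchitectureSpec, seed: int, dtype=np.float32) -> Network:
    """Deterministically initialized network for a given seed."""
    ss = np.random.SeedSequence([int(seed), 0x5EED])
    children = ss.spawn(spec.n_temporal_conv + 4)
    layers = []
    in_f = 1
    ci = 0
    for i in range(spec.n_temporal_conv):
        rng = np.random.default_rng(children[ci]); ci += 1
        layers.append(TemporalConv(in_f, spec.filters, spec.temporal_kernel, rng,
                                   name=f"conv{i + 1}", dtype=dtype))
        layers.append(ReLU(name=f"relu{i + 1}"))
        if i < spec.n_pooled_blocks:
            layers.append(MaxPoolTime(name=f"pool{i + 1}"))
        in_f = spec.filters
    rng = np.random.default_rng(children[ci]); ci += 1
    layers.append(SpatialConv(spec.n_channels, spec.filters, spec.filters, rng, dtype=dtype))
    layers.append(ReLU(name="srelu"))
    layers.append(Flatten())
    rng = np.random.default_rng(children[ci]); ci += 1
    layers.append(Dense(spec.flatten_size(), spec.dense_units, rng, name="dense1", dtype=dtype))
    layers.append(ReLU(name="drelu"))
    drop_rng = np.random.default_rng(children[ci]); ci += 1
    layers.append(Dropout(spec.dropout, drop_rng))
    rng = np.random.default_rng(children[ci]); ci += 1
    layers.append(Dense(spec.dense_units, spec.n_classes, rng, name="out",
                        dtype=dtype, init="xavier"))
    return Network(layers)


@dataclass
class FoldResult:
    """Held-out performance of one cross-validation fold."""

    fold: int
    accuracy: float  # percent
    test_idx: np.ndarray
    y_pred: np.ndarray


class EEGDecoder(ClassifierMixin, BaseEstimator):
    """CNN classifier for (n_trials, 250, 62) epochs.

    Parameters
    ----------
    lr, batch_size, max_epochs : Adam training recipe.
    patience : early-stopping patience (epochs without validation-accuracy
        improvement); ``0`` disables early stopping and the validation split.
    val_fraction : fraction of the training data held out for early stopping.
    seed : controls initialization, shuffling, dropout and the validation
        split; two fits with identical data and seed are identical.

    Attributes
    ----------
    net_ : the trained :class:`~eegxai._nn.Network` (float32).
    classes_, scale_, history_ : label set, input scale (a single standard
        deviation used to normalize the uV input), per-epoch training log.
    """

    def __init__(self, spec: ArchitectureSpec | None = None, lr: float = 1e-3,
                 batch_size: int = 64, max_epochs: int = 30, patience: int = 5,
                 val_fraction: float = 0.1, seed: int = 0, verbose: bool = False):
        self.spec = spec
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed
        self.verbose = verbose

    # -- scikit-learn API --------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be (n_trials, n_samples, n_channels)")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        spec = self.spec or ArchitectureSpec(n_classes=len(self.classes_))
        if spec.n_classes != len(self.classes_):
            spec = replace(spec, n_classes=len(self.classes_))
        if X.shape[1:] != (spec.n_samples, spec.n_channels):
            raise ValueError(
                f"X trials must be {spec.n_samples} x {spec.n_channels}, got {X.shape[1:]}"
            )
        self.spec_ = spec
        self.scale_ = float(X.std()) or 1.0
        net = build_network(spec, self.seed)
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0x7A1]))

        Xs = (X / self.scale_).astype(np.float32)[..., None]
        if self.patience and len(y_enc) >= 10 * len(self.classes_):
            tr_idx, va_idx = train_test_split(
                np.arange(len(y_enc)), test_size=self.val_fraction,
                stratify=y_enc, random_state=int(self.seed) % 2**32,
            )
        else:
            tr_idx, va_idx = np.arange(len(y_enc)), np.array([], dtype=int)

        opt = Adam(net, lr=self.lr)
        best_val = -np.inf
        best_weights = None
        since_best = 0
        history = []
        B = self.batch_size
        for epoch in range(self.max_epochs):
            order = rng.permutation(tr_idx)
            losses = []
            for lo in range(0, order.size, B):
                idx = order[lo:lo + B]
                logits = net.forward(Xs[idx], train=True)
                loss, g = cross_entropy(logits, y_enc[idx])
                net.backward(g, accumulate=True, need_input_grad=False)
                opt.step()
                losses.append(loss)
            row = {"epoch": epoch, "loss": float(np.mean(losses))}
            if va_idx.size:
                acc = self._eval_accuracy(net, Xs[va_idx], y_enc[va_idx])
                row["val_accuracy"] = acc
                if acc > best_val + 1e-12:
                    best_val = acc
                    best_weights = net.get_weights()
                    since_best = 0
                else:
                    since_best += 1
            history.append(row)
            if self.verbose:
                print(f"epoch {epoch}: " + ", ".join(f"{k}={v:.4g}" for k, v in row.items() if k != "epoch"))
            if va_idx.size and self.patience and since_best >= self.patience:
                break
        if best_weights is not None:
            net.set_weights(best_weights)
        net.clear_caches()
        self.net_ = net
        self.history_ = history
        self._net64_cache = None  # invalidate any attribution-time copy
        return self

    def _eval_accuracy(self, net: Network, Xs: np.ndarray, y: np.ndarray) -> float:
        B = self.batch_size
        preds = []
        for lo in range(0, Xs.shape[0], B):
            logits = net.forward(Xs[lo:lo + B], train=False)
            preds.append(np.argmax(logits, axis=1))
        return float(np.mean(np.concatenate(preds) == y))

    def decision_function(self, X):
        """Pre-softmax class scores (logits)."""
        check_is_fitted(self, "net_")
        X = np.asarray(X)
        Xs = (X / self.scale_).astype(np.float32)[..., None]
        out = []
        step = self.batch_size
        for lo in range(0, Xs.shape[0], step):
            out.append(self.net_.forward(Xs[lo:lo + step], train=False))
        self.net_.clear_caches()
        return np.concatenate(out)

    def predict_proba(self, X):
        return softmax(self.decision_function(X).astype(np.float64))

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def save_decoder(decoder: EEGDecoder, path) -> None:
    """Persist a fitted decoder (weights + spec + training config) to .npz."""
    import json

    check_is_fitted(decoder, "net_")
    meta = {
        "spec": {k: getattr(decoder.spec_, k) for k in (
            "n_temporal_conv", "filters", "temporal_kernel", "pool", "n_pooled_blocks",
            "n_channels", "n_samples", "dense_units", "dropout", "n_classes")},
        "params": {k: v for k, v in decoder.get_params(deep=False).items() if k != "spec"},
        "scale": decoder.scale_,
        "classes": np.asarray(decoder.classes_).tolist(),
        "history": decoder.history_,
    }
    arrays = {f"w::{k}": v for k, v in decoder.net_.get_weights().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_decoder(path) -> EEGDecoder:
    """Load a decoder checkpoint written by :func:`save_decoder`."""
    import json

    with np.load(path) as fh:
        meta = json.loads(bytes(fh["__meta__"]).decode())
        weights = {k[3:]: fh[k] for k in fh.files if k.startswith("w::")}
    dec = EEGDecoder(**meta["params"])
    dec.spec_ = ArchitectureSpec(**meta["spec"])
    dec.classes_ = np.asarray(meta["classes"])
    dec.scale_ = float(meta["scale"])
    dec.history_ = meta["history"]
    dec.net_ = build_network(dec.spec_, int(meta["params"].get("seed", 0)))
    dec.net_.set_weights(weights)
    return dec


def _clone_cfg(decoder: EEGDecoder, **overrides) -> EEGDecoder:
    params = decoder.get_params(deep=False)
    params.update(overrides)
    return EEGDecoder(**params)


def cross_validate(X, y, k: int = 5, seed: int = 0, decoder: EEGDecoder | None = None,
                   ) -> list[tuple[EEGDecoder, FoldResult]]:
    """Stratified k-fold cross-validation of the decoder.

    Each fold's decoder is trained only on its training split; accuracy is
    computed on the held-out split (percent).  Folds partition all trials.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise ValueError("k exceeds the number of trials in the smallest class")
    proto = decoder if decoder is not None else EEGDecoder(seed=seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % 2**32)
    results = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        dec = _clone_cfg(proto, seed=int(proto.seed) + fold)
        dec.fit(X[tr], y[tr])
        y_pred = dec.predict(X[te])
        acc = 100.0 * float(np.mean(y_pred == y[te]))
        results.append((dec, FoldResult(fold=fold, accuracy=acc, test_idx=te, y_pred=y_pred)))
    return results


def retrain_with_permuted_labels(X, y, k: int = 5, seed: int = 0,
                                 decoder: EEGDecoder | None = None,
                                 permutation_seed: int | None = None,
                                 ) -> list[tuple[EEGDecoder, FoldResult]]:
    """Label-randomization control: permute training labels, retrain fully.

    ``seed`` fixes the fold structure (use the same seed as the matching
    :func:`cross_validate` call so original and control models share test
    splits); ``permutation_seed`` (default: derived from ``seed``) drives
    the label permutation, a bijection on the training split so the label
    multiset is unchanged.  Held-out trials keep their true labels, so the
    reported accuracy measures what the permuted model transfers to real
    structure (chance, for a successful randomization).
    """
    X = np.asarray(X)
    y = np.asarray(y)
    proto = decoder if decoder is not None else EEGDecoder(seed=seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % 2**32)
    if permutation_seed is None:
        permutation_seed = seed
    rng = np.random.default_rng(np.random.SeedSequence([int(permutation_seed), 0xBAD1ABE1]))
    results = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        y_perm = y[tr][rng.permutation(tr.size)]
        dec = _clone_cfg(proto, seed=int(proto.seed) + fold)
        dec.fit(X[tr], y_perm)
        y_pred = dec.predict(X[te])
        acc = 100.0 * float(np.mean(y_pred == y[te]))
        results.append((dec, FoldResult(fold=fold, accuracy=acc, test_idx=te, y_pred=y_pred)))
    return results


def reinitialize_weights(decoder: EEGDecoder, seed: int) -> EEGDecoder:
    """Weight-randomization control: re-draw all parameters, no retraining."""
    check_is_fitted(decoder, "net_")
    fresh = _clone_cfg(decoder, seed=seed)
    fresh.classes_ = decoder.classes_
    fresh.spec_ = decoder.spec_
    fresh.scale_ = decoder.scale_
    fresh.net_ = build_network(decoder.spec_, seed)
    fresh.history_ = []
    return fresh
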