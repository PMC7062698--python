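"""Compact two-block convolutional classifier for single-trial EEG.

The architecture is the EEGNet family design: block 1 learns temporal
band-pass-like filters (plain temporal convolution, width 64 samples)
followed by depthwise spatial filters spanning all channels (D spatial
filters per temporal filter); block 2 is a separable convolution
(depthwise temporal width 16, then pointwise). Batch normalization, ELU
activations, average pooling (4 then 8) and dropout follow each block; a
dense softmax layer over the four trial classes closes the network.

Forward and backward passes are written directly in NumPy: the network
is small enough that explicit im2col convolutions with hand-derived
gradients train in seconds per epoch on one CPU, and exposing the exact
backward pass makes input-gradient saliency a first-class operation
rather than a framework detour.

Convolutions carry no bias (each is immediately followed by batch
normalization). Max-norm constraints of 1.0 on the depthwise spatial
weights and 0.25 on the dense layer regularize cross-subject training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.fft as sfft
from numpy.lib.stride_tricks import sliding_window_view

from ..core import EpochSet

__all__ = [
    "NetConfig",
    "EEGNet",
    "TrainedModel",
    "build_model",
    "class_weights",
    "train",
    "predict",
    "select_filter_config",
]

_BN_EPS = 1e-3
_BN_MOMENTUM = 0.99


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters.

    F1 temporal filters, D spatial filters per temporal filter and
    F2 = F1*D separable filters. The two published filter-count options
    are (F1, D) = (8, 2) and (4, 2).
    """

    F1: int = 8
    D: int = 2
    temporal_kernel: int = 64
    separable_kernel: int = 16
    pool1: int = 4
    pool2: int = 8
    dropout_p: float = 0.25
    n_classes: int = 4

    @property
    def F2(self) -> int:
        return self.F1 * self.D


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int, dtype=np.float32) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # d/dx elu = 1 for x>0, elu(x)+1 otherwise
    return np.where(x > 0, 1.0, y + 1.0).astype(x.dtype, copy=False)


class EEGNet:
    """The network for inputs of shape (channels C, timepoints T)."""

    def __init__(self, cfg: NetConfig, C: int, T: int, seed: int = 0,
                 dtype=np.float32) -> None:
        if T < cfg.temporal_kernel:
            raise ValueError(
                f"T={T} shorter than the temporal kernel "
                f"({cfg.temporal_kernel} samples)"
            )
        if C < 2:
            raise ValueError("need at least 2 channels")
        self.cfg = cfg
        self.C = C
        self.T = T
        self.T4 = T // cfg.pool1
        self.T32 = self.T4 // cfg.pool2
        self.n_flat = cfg.F2 * self.T32
        if self.T32 < 1:
            raise ValueError("T too short for the pooling cascade")

        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        F1, D, F2 = cfg.F1, cfg.D, cfg.F2
        K1, K2 = cfg.temporal_kernel, cfg.separable_kernel
        self.params: dict[str, np.ndarray] = {
            "w_conv1": _glorot(rng, (F1, K1), K1, F1, self.dtype),
            "gamma1": np.ones(F1, dtype=self.dtype),
            "beta1": np.zeros(F1, dtype=self.dtype),
            "w_dw": _glorot(rng, (F1, D, C), C, D, self.dtype),
            "gamma2": np.ones(F2, dtype=self.dtype),
            "beta2": np.zeros(F2, dtype=self.dtype),
            "w_sep_d": _glorot(rng, (F2, K2), K2, 1, self.dtype),
            "w_sep_p": _glorot(rng, (F2, F2), F2, F2, self.dtype),
            "gamma3": np.ones(F2, dtype=self.dtype),
            "beta3": np.zeros(F2, dtype=self.dtype),
            "w_fc": _glorot(rng, (cfg.n_classes, self.n_flat),
                            self.n_flat, cfg.n_classes, self.dtype),
            "b_fc": np.zeros(cfg.n_classes, dtype=self.dtype),
        }
        self.running: dict[str, np.ndarray] = {
            "mean1": np.zeros(F1, dtype=self.dtype),
            "var1": np.ones(F1, dtype=self.dtype),
            "mean2": np.zeros(F2, dtype=self.dtype),
            "var2": np.ones(F2, dtype=self.dtype),
            "mean3": np.zeros(F2, dtype=self.dtype),
            "var3": np.ones(F2, dtype=self.dtype),
        }

    # -- bookkeeping --------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        """Trainable parameter count (running statistics excluded)."""
        return sum(p.size for p in self.params.values())

    def state(self) -> dict:
        return {
            "params": {k: v.copy() for k, v in self.params.items()},
            "running": {k: v.copy() for k, v in self.running.items()},
        }

    def load_state(self, state: dict) -> None:
        self.params = {k: v.copy() for k, v in state["params"].items()}
        self.running = {k: v.copy() for k, v in state["running"].items()}

    # -- batch normalization ------------------------------------------------

    def _bn_forward(self, x: np.ndarray, idx: str, axes: tuple[int, ...],
                    training: bool, cache: dict) -> np.ndarray:
        gamma = self.params[f"gamma{idx}"]
        beta = self.params[f"beta{idx}"]
        shape = [1] * x.ndim
        shape[1] = x.shape[1]
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            rm, rv = self.running[f"mean{idx}"], self.running[f"var{idx}"]
            rm *= _BN_MOMENTUM
            rm += (1 - _BN_MOMENTUM) * mu
            rv *= _BN_MOMENTUM
            rv += (1 - _BN_MOMENTUM) * var
        else:
            mu = self.running[f"mean{idx}"]
            var = self.running[f"var{idx}"]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mu.reshape(shape)) * inv_std.reshape(shape)
        xhat = xhat.astype(self.dtype, copy=False)
        cache[f"bn{idx}"] = (xhat, inv_std.astype(self.dtype), axes, training)
        return gamma.reshape(shape) * xhat + beta.reshape(shape)

    def _bn_backward(self, dy: np.ndarray, idx: str, cache: dict,
                     grads: dict) -> np.ndarray:
        xhat, inv_std, axes, training = cache[f"bn{idx}"]
        gamma = self.params[f"gamma{idx}"]
        shape = [1] * dy.ndim
        shape[1] = dy.shape[1]
        grads[f"gamma{idx}"] = (dy * xhat).sum(axis=axes)
        grads[f"beta{idx}"] = dy.sum(axis=axes)
        dxhat = dy * gamma.reshape(shape)
        if not training:
            return dxhat * inv_std.reshape(shape)
        m = dy.size // dy.shape[1]
        s1 = dxhat.sum(axis=axes).reshape(shape)
        s2 = (dxhat * xhat).sum(axis=axes).reshape(shape)
        return (inv_std.reshape(shape) / m) * (m * dxhat - s1 - xhat * s2)

    # -- forward ------------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None
                ) -> tuple[np.ndarray, dict]:
        """Compute logits (pre-softmax scores); returns (logits, cache)."""
        cfg = self.cfg
        n, c, t = x.shape
        if (c, t) != (self.C, self.T):
            raise ValueError(
                f"input shape ({c}, {t}) does not match model "
                f"({self.C}, {self.T})"
            )
        if training and rng is None:
            rng = np.random.default_rng()
        x = np.ascontiguousarray(x, dtype=self.dtype)
        cache: dict = {"training": training}
        K1, K2 = cfg.temporal_kernel, cfg.separable_kernel
        padl1, padr1 = (K1 - 1) // 2, K1 // 2
        padl2, padr2 = (K2 - 1) // 2, K2 // 2

        # block 1: temporal convolution (same padding, cross-correlation),
        # computed in the frequency domain: the wide kernel makes im2col
        # memory-bound while FFT convolution touches each sample once.
        # y[t] = sum_k w[k] x[t + k - padl1]  ==  conv(x, flip(w))[t + padr1]
        nfft = sfft.next_fast_len(t + K1 - 1)
        xf = sfft.rfft(x, nfft, axis=-1)  # (N, C, nf)
        wf = sfft.rfft(self.params["w_conv1"][:, ::-1], nfft, axis=-1)
        full = sfft.irfft(
            xf[:, None, :, :] * wf[None, :, None, :], nfft, axis=-1
        )  # (N, F1, C, nfft)
        z1 = np.ascontiguousarray(full[..., padr1 : padr1 + t])
        cache["xf"], cache["nfft"] = xf, nfft
        y1 = self._bn_forward(z1, "1", (0, 2, 3), training, cache)
        cache["y1"] = y1

        # depthwise spatial filters spanning all channels (valid);
        # batched (D, C) @ (C, T) matmul per temporal map
        z2 = np.matmul(self.params["w_dw"][None], y1)  # (N, F1, D, T)
        z2 = z2.reshape(n, cfg.F2, self.T)
        y2 = self._bn_forward(z2, "2", (0, 2), training, cache)
        a2 = _elu(y2).astype(self.dtype, copy=False)
        cache["y2"], cache["a2"] = y2, a2
        p2 = a2[:, :, : self.T4 * cfg.pool1].reshape(
            n, cfg.F2, self.T4, cfg.pool1
        ).mean(axis=-1)
        if training and cfg.dropout_p > 0:
            mask = (rng.random(p2.shape, dtype=np.float32)
                    >= cfg.dropout_p).astype(self.dtype) / (1 - cfg.dropout_p)
            p2 = p2 * mask
            cache["drop1"] = mask
        cache["p2"] = p2

        # block 2: separable convolution (depthwise temporal + pointwise)
        pp = np.pad(p2, ((0, 0), (0, 0), (padl2, padr2)))
        s2 = np.ascontiguousarray(
            sliding_window_view(pp, K2, axis=-1)
        )  # (N, F2, T4, K2)
        zd = np.einsum("nftk,fk->nft", s2, self.params["w_sep_d"])
        zp = np.matmul(self.params["w_sep_p"][None], zd)  # (N, F2, T4)
        cache["s2"], cache["zd"] = s2, zd
        y3 = self._bn_forward(zp, "3", (0, 2), training, cache)
        a3 = _elu(y3).astype(self.dtype, copy=False)
        cache["y3"], cache["a3"] = y3, a3
        p3 = a3[:, :, : self.T32 * cfg.pool2].reshape(
            n, cfg.F2, self.T32, cfg.pool2
        ).mean(axis=-1)
        if training and cfg.dropout_p > 0:
            mask = (rng.random(p3.shape) >= cfg.dropout_p).astype(
                self.dtype
            ) / (1 - cfg.dropout_p)
            p3 = p3 * mask
            cache["drop2"] = mask
        flat = p3.reshape(n, self.n_flat)
        cache["flat"] = flat
        logits = flat @ self.params["w_fc"].T + self.params["b_fc"]
        return logits.astype(self.dtype, copy=False), cache

    # -- backward -----------------------------------------------------------

    def backward(self, dlogits: np.ndarray, cache: dict,
                 want_input_grad: bool = False
                 ) -> tuple[dict[str, np.ndarray], np.ndarray | None]:
        """Backpropagate; returns (parameter gradients, input gradient)."""
        cfg = self.cfg
        n = dlogits.shape[0]
        K1, K2 = cfg.temporal_kernel, cfg.separable_kernel
        padl1 = (K1 - 1) // 2
        padl2 = (K2 - 1) // 2
        grads: dict[str, np.ndarray] = {}
        dlogits = dlogits.astype(self.dtype)

        flat = cache["flat"]
        grads["w_fc"] = dlogits.T @ flat
        grads["b_fc"] = dlogits.sum(axis=0)
        dflat = dlogits @ self.params["w_fc"]
        dp3 = dflat.reshape(n, cfg.F2, self.T32)
        if "drop2" in cache:
            dp3 = dp3 * cache["drop2"]
        da3 = np.zeros((n, cfg.F2, self.T4), dtype=self.dtype)
        da3[:, :, : self.T32 * cfg.pool2] = np.repeat(
            dp3 / cfg.pool2, cfg.pool2, axis=-1
        )
        dy3 = da3 * _elu_grad(cache["y3"], cache["a3"])
        dzp = self._bn_backward(dy3, "3", cache, grads).astype(self.dtype, copy=False)

        # pointwise then depthwise temporal
        zd = cache["zd"]
        grads["w_sep_p"] = np.matmul(
            dzp, zd.transpose(0, 2, 1)
        ).sum(axis=0)
        dzd = np.matmul(
            self.params["w_sep_p"].T[None], dzp
        ).astype(self.dtype, copy=False)
        grads["w_sep_d"] = np.einsum("nft,nftk->fk", dzd, cache["s2"])
        t4 = self.T4
        dpp = np.zeros((n, cfg.F2, t4 + K2 - 1), dtype=self.dtype)
        wd = self.params["w_sep_d"]
        for k in range(K2):
            dpp[:, :, k : k + t4] += wd[None, :, k, None] * dzd
        dp2 = dpp[:, :, padl2 : padl2 + t4]
        if "drop1" in cache:
            dp2 = dp2 * cache["drop1"]
        da2 = np.zeros((n, cfg.F2, self.T), dtype=self.dtype)
        da2[:, :, : self.T4 * cfg.pool1] = np.repeat(
            dp2 / cfg.pool1, cfg.pool1, axis=-1
        )
        dy2 = da2 * _elu_grad(cache["y2"], cache["a2"])
        dz2 = self._bn_backward(dy2, "2", cache, grads).astype(self.dtype, copy=False)
        dz2 = dz2.reshape(n, cfg.F1, cfg.D, self.T)

        y1 = cache["y1"]
        # batched (D, T) @ (T, C) and (C, D) @ (D, T) matmuls per map
        grads["w_dw"] = np.matmul(
            dz2, y1.transpose(0, 1, 3, 2)
        ).sum(axis=0)
        dy1 = np.matmul(
            self.params["w_dw"].transpose(0, 2, 1)[None], dz2
        ).astype(self.dtype, copy=False)
        dz1 = self._bn_backward(dy1, "1", cache, grads).astype(self.dtype, copy=False)

        # temporal convolution, frequency domain:
        # dW[f,k] = sum_{n,c,t} x[n,c,t+k-padl1] dz1[n,f,c,t]
        #         = irfft(sum_{n,c} conj(XF) * DF)[(k - padl1) mod nfft]
        xf, nfft = cache["xf"], cache["nfft"]
        df = sfft.rfft(dz1, nfft, axis=-1)  # (N, F1, C, nf)
        corr = sfft.irfft(
            np.einsum("ncq,nfcq->fq", np.conj(xf), df), nfft, axis=-1
        )  # (F1, nfft); entry m holds sum_t x[t] dz1[t + m]
        lags = (padl1 - np.arange(K1)) % nfft
        grads["w_conv1"] = corr[:, lags]
        dx = None
        if want_input_grad:
            # dx = sum_f conv(dz1[f], w[f])[t + padl1]
            wf2 = sfft.rfft(self.params["w_conv1"], nfft, axis=-1)
            prod = np.einsum("nfcq,fq->ncq", df, wf2)
            dx = sfft.irfft(prod, nfft, axis=-1)[..., padl1 : padl1 + self.T]
            dx = np.ascontiguousarray(dx, dtype=self.dtype)
        grads = {k: v.astype(self.dtype, copy=False) for k, v in grads.items()}
        return grads, dx

    def apply_maxnorm(self) -> None:
        """Project depthwise (1.0) and dense (0.25) weights onto norm balls."""
        w = self.params["w_dw"]
        norms = np.linalg.norm(w, axis=2, keepdims=True)
        np.divide(w, np.maximum(norms, 1.0), out=w)
        w = self.params["w_fc"]
        norms = np.linalg.norm(w, axis=1, keepdims=True)
        np.divide(w, np.maximum(norms / 0.25, 1.0), out=w)


def build_model(cfg: NetConfig, C: int, T: int, seed: int = 0,
                dtype=np.float32) -> EEGNet:
    """Construct the network for C channels and T timepoints."""
    return EEGNet(cfg, C, T, seed=seed, dtype=dtype)


def class_weights(label_counts: np.ndarray) -> np.ndarray:
    """Inverse-proportion class weights with the majority class at 1."""
    counts = np.asarray(label_counts, dtype=np.float64)
    if np.any(counts <= 0):
        raise ValueError("every class must have at least one training trial")
    return counts.max() / counts


def _softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _weighted_ce(logits: np.ndarray, y: np.ndarray,
                 sample_w: np.ndarray | None
                 ) -> tuple[float, np.ndarray]:
    """Mean (weighted) cross-entropy and its gradient w.r.t. logits."""
    n = len(y)
    p = _softmax(logits.astype(np.float64))
    logp = np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    w = np.ones(n) if sample_w is None else sample_w
    loss = float(-(w * logp).mean())
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / n)[:, None]
    return loss, dlogits


@dataclass
class TrainedModel:
    """Network weights at the best-validation epoch plus training history."""

    model: EEGNet
    history: pd.DataFrame  # columns: epoch, train_loss, val_loss
    best_epoch: int

    @property
    def config(self) -> NetConfig:
        return self.model.cfg


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= (
                self.lr * (self.m[k] / b1t)
                / (np.sqrt(self.v[k] / b2t) + self.eps)
            ).astype(params[k].dtype)


def _eval_loss(model: EEGNet, x: np.ndarray, y: np.ndarray,
               batch_size: int = 64) -> float:
    total, n = 0.0, len(y)
    for i in range(0, n, batch_size):
        logits, _ = model.forward(x[i : i + batch_size], training=False)
        loss, _ = _weighted_ce(logits, y[i : i + batch_size], None)
        total += loss * len(y[i : i + batch_size])
    return total / n


def train(
    model: EEGNet,
    train_set: EpochSet,
    val_set: EpochSet,
    max_epochs: int = 500,
    batch_size: int = 32,
    lr: float = 1e-3,
    seed: int = 0,
) -> TrainedModel:
    """ADAM training of the class-weighted cross-entropy.

    After every epoch the validation cross-entropy is recorded; the
    returned weights are those of the epoch with the lowest validation
    loss (best-checkpoint early stopping).
    """
    if val_set.n_trials == 0:
        raise ValueError("validation set is empty")
    if set(train_set.labels) != set(val_set.labels):
        raise ValueError("train and validation label sets differ")
    counts = np.bincount(train_set.labels, minlength=model.cfg.n_classes)
    cw = class_weights(counts)  # raises if a class is missing

    xtr = np.ascontiguousarray(train_set.data, dtype=model.dtype)
    ytr = train_set.labels
    xval = np.ascontiguousarray(val_set.data, dtype=model.dtype)
    yval = val_set.labels
    sample_w = cw[ytr]

    rng = np.random.default_rng(seed)
    opt = _Adam(model.params, lr=lr)
    history = {"epoch": [], "train_loss": [], "val_loss": []}
    best_loss, best_epoch, best_state = np.inf, -1, model.state()

    n = len(ytr)
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            logits, cache = model.forward(xtr[idx], training=True, rng=rng)
            loss, dlogits = _weighted_ce(logits, ytr[idx], sample_w[idx])
            grads, _ = model.backward(dlogits, cache)
            opt.step(model.params, grads)
            model.apply_maxnorm()
            epoch_loss += loss * len(idx)
        val_loss = _eval_loss(model, xval, yval)
        history["epoch"].append(epoch)
        history["train_loss"].append(epoch_loss / n)
        history["val_loss"].append(val_loss)
        if val_loss < best_loss:
            best_loss, best_epoch = val_loss, epoch
            best_state = model.state()

    model.load_state(best_state)
    return TrainedModel(
        model=model, history=pd.DataFrame(history), best_epoch=best_epoch
    )


def predict(
    trained: TrainedModel | EEGNet,
    epochs: EpochSet | np.ndarray,
    batch_size: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and pre-softmax scores for each trial.

    Dropout is disabled and batch normalization uses running statistics,
    so repeated calls on fixed weights are identical.
    """
    model = trained.model if isinstance(trained, TrainedModel) else trained
    x = epochs.data if isinstance(epochs, EpochSet) else np.asarray(epochs)
    if x.ndim != 3 or x.shape[1:] != (model.C, model.T):
        raise ValueError(
            f"epochs shaped {x.shape[1:]} do not match model "
            f"({model.C}, {model.T})"
        )
    scores = np.empty((x.shape[0], model.cfg.n_classes), dtype=model.dtype)
    for i in range(0, x.shape[0], batch_size):
        logits, _ = model.forward(
            np.ascontiguousarray(x[i : i + batch_size], dtype=model.dtype)
        )
        scores[i : i + batch_size] = logits
    probs = _softmax(scores.astype(np.float64))
    return probs, scores


def input_gradient(
    trained: TrainedModel | EEGNet,
    x: np.ndarray,
    class_indices: np.ndarray,
    batch_size: int = 64,
) -> np.ndarray:
    """Gradient of each trial's pre-softmax class score w.r.t. the input.

    ``class_indices`` selects the score whose gradient is taken, one per
    trial. Evaluation mode (no dropout, running batch-norm statistics).
    """
    model = trained.model if isinstance(trained, TrainedModel) else trained
    x = np.asarray(x, dtype=model.dtype)
    class_indices = np.asarray(class_indices, dtype=np.int64)
    out = np.empty_like(x)
    for i in range(0, x.shape[0], batch_size):
        xb = np.ascontiguousarray(x[i : i + batch_size])
        cb = class_indices[i : i + batch_size]
        _, cache = model.forward(xb, training=False)
        dlogits = np.zeros((len(cb), model.cfg.n_classes), dtype=model.dtype)
        dlogits[np.arange(len(cb)), cb] = 1.0
        _, dx = model.backward(dlogits, cache, want_input_grad=True)
        out[i : i + batch_size] = dx
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite input gradients")
    return out


def select_filter_config(
    dataset: dict[str, EpochSet],
    candidates: list[tuple[int, int]] = [(4, 2), (8, 2)],
    *,
    n_val: int = 4,
    seed: int = 0,
    **train_params,
) -> NetConfig:
    """Pick the (F1, D) option with the higher mean LOOS accuracy.

    Ties resolve toward the larger F1. A single candidate is returned
    without running the evaluation.
    """
    if not candidates:
        raise ValueError("need at least one candidate configuration")
    if len(candidates) == 1:
        f1, d = candidates[0]
        return NetConfig(F1=f1, D=d)
    from ..evaluation import run_loos  # local import to avoid a cycle

    best_cfg, best_key = None, None
    for f1, d in candidates:
        cfg = NetConfig(F1=f1, D=d)
        _, summary = run_loos(dataset, cfg, n_val=n_val, seed=seed,
                              **train_params)
        key = (summary.mean_accuracy, f1)
        if best_key is None or key > best_key:
            best_cfg, best_key = cfg, key
    return best_cfg
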