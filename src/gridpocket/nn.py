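"""A compact CPU trainer for small 3D convolutional networks.

Implements exactly what the block classifier needs: Conv3D (stride 1,
Keras-style 'same' padding, evaluated via FFT), ReLU, 2³ max pooling,
inverted dropout, dense layers, a sigmoid/binary-cross-entropy head and Adam.
Everything is float32 and fully deterministic given a seed.

The convolution and both of its gradients are linear convolutions evaluated
with zero-padded real FFTs; the transform length per axis is chosen so that
forward, input-gradient and weight-gradient products are all wrap-around free
and can share one cached spectrum of the layer input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfftn, next_fast_len, rfftn

_AXES = (2, 3, 4)


def _flip3(a: np.ndarray) -> np.ndarray:
    return a[..., ::-1, ::-1, ::-1]


class Layer:
    """Base layer; stateful between forward and backward."""

    params: tuple[str, ...] = ()

    def forward(self, x: np.ndarray, *, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        raise NotImplementedError


class Conv3D(Layer):
    """3D correlation, stride 1, 'same' output size (left pad (k−1)//2, right pad k//2)."""

    params = ("W", "b")

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel**3
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel, kernel, kernel)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.plo = (kernel - 1) // 2
        self.phi = kernel // 2

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def _lengths(self, spatial, train: bool):
        # forward/input-gradient products need >= D+k-1 points per axis; the
        # weight gradient re-uses the cached input spectrum and needs >= 2D-1
        if train:
            return [next_fast_len(max(2 * d - 1, d + self.k - 1)) for d in spatial]
        return [next_fast_len(d + self.k - 1) for d in spatial]

    def forward(self, x, *, train=False, rng=None):
        self.spatial = x.shape[2:]
        L = self._lengths(self.spatial, train)
        xhat = rfftn(x, s=L, axes=_AXES)
        if train:
            self._xhat, self._L = xhat, L
        khat = rfftn(_flip3(self.W), s=L, axes=_AXES)
        yfull = irfftn(
            np.einsum("ncxyz,fcxyz->nfxyz", xhat, khat), s=L, axes=_AXES
        )
        sl = tuple(slice(self.phi, self.phi + d) for d in self.spatial)
        return yfull[(slice(None), slice(None)) + sl] + self.b[None, :, None, None, None]

    def backward(self, dy):
        L = self._L
        k, plo = self.k, self.plo
        self.db = dy.sum(axis=(0, 2, 3, 4))
        dyhat = rfftn(dy, s=L, axes=_AXES)
        khat_u = rfftn(self.W, s=L, axes=_AXES)
        dxfull = irfftn(
            np.einsum("nfxyz,fcxyz->ncxyz", dyhat, khat_u), s=L, axes=_AXES
        )
        sl = tuple(slice(plo, plo + d) for d in self.spatial)
        dx = dxfull[(slice(None), slice(None)) + sl]
        fdyhat = rfftn(_flip3(dy), s=L, axes=_AXES)
        dwfull = irfftn(
            np.einsum("nfxyz,ncxyz->fcxyz", fdyhat, self._xhat), s=L, axes=_AXES
        )
        slw = tuple(slice(d - 1 - plo, d - 1 - plo + k) for d in self.spatial)
        self.dW = dwfull[(slice(None), slice(None)) + slw]
        self._xhat = None
        return dx

    def out_shape(self, in_shape):
        return (self.out_ch,) + tuple(in_shape[1:])


class ReLU(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)

    def out_shape(self, in_shape):
        return tuple(in_shape)


class MaxPool3D(Layer):
    """2×2×2 max pooling; gradient routed to the (first) argmax of each window."""

    def forward(self, x, *, train=False, rng=None):
        n, c, d, h, w = x.shape
        self._in_shape = x.shape
        xr = (
            x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(n, c, d // 2, h // 2, w // 2, 8)
        )
        self._arg = xr.argmax(axis=-1)
        return xr.max(axis=-1)

    def backward(self, dy):
        n, c, d, h, w = self._in_shape
        flat = np.zeros(dy.shape + (8,), dtype=dy.dtype)
        np.put_along_axis(flat, self._arg[..., None], dy[..., None], axis=-1)
        return (
            flat.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(n, c, d, h, w)
        )

    def out_shape(self, in_shape):
        c, d, h, w = in_shape
        return (c, d // 2, h // 2, w // 2)


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, *, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate).astype(x.dtype) / (1 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def out_shape(self, in_shape):
        return tuple(in_shape)


class Flatten(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)


class Dense(Layer):
    params = ("W", "b")

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_features), (in_features, out_features)).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        self._x = None
        return dy @ self.W.T

    def out_shape(self, in_shape):
        return (self.W.shape[1],)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def binary_cross_entropy(p: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}

    def step(self, layers: list[Layer]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, layer in enumerate(layers):
            for name in layer.params:
                w = getattr(layer, name)
                g = getattr(layer, "d" + name)
                m, v = self.state.get((i, name), (np.zeros_like(w), np.zeros_like(w)))
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                self.state[(i, name)] = (m, v)
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                w -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(w.dtype)


@dataclass
class EpochStats:
    epoch: int
    loss: float
    accuracy: float
    val_loss: float | None = None
    val_accuracy: float | None = None


class Network:
    """A sequential stack ending in a 1-unit sigmoid head, trained with
    Adam on binary cross-entropy."""

    def __init__(self, layers: list[Layer], seed: int = 0, fingerprint: str = ""):
        self.layers = layers
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.fingerprint = fingerprint
        self.history: list[EpochStats] = []

    # -- inference ---------------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=self.rng)
        return x[:, 0]

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        out = np.empty(len(x))
        for i in range(0, len(x), batch_size):
            out[i : i + batch_size] = sigmoid(self.forward_logits(x[i : i + batch_size]))
        return out

    def shape_trace(self, in_shape=(4, 16, 16, 16)) -> list[tuple[int, ...]]:
        """Per-layer output shapes (channel-first, batch omitted)."""
        shapes = [tuple(in_shape)]
        cur = tuple(in_shape)
        for layer in self.layers:
            cur = layer.out_shape(cur)
            shapes.append(cur)
        return shapes

    # -- training ----------------------------------------------------------
    def _backward(self, dz: np.ndarray) -> None:
        grad = dz[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def evaluate(self, x: np.ndarray, y: np.ndarray, batch_size: int = 64) -> tuple[float, float]:
        p = self.predict_proba(x, batch_size=batch_size)
        return binary_cross_entropy(p, y), float(np.mean((p >= 0.5) == (y >= 0.5)))

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        validation: tuple[np.ndarray, np.ndarray] | None = None,
        epochs: int = 5,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        patience: int | None = 1,
        min_delta: float = 1e-4,
        monitor: str = "val_accuracy",
        shuffle_seed: int | None = None,
        stop_at_accuracy: float | None = None,
    ) -> "Network":
        """Mini-batch Adam training with early stopping on a validation metric.

        ``monitor`` is ``val_accuracy`` (default) or ``val_loss``; the weights
        of the first best epoch are restored when training ends.
        """
        if monitor not in ("val_accuracy", "val_loss"):
            raise ValueError("monitor must be val_accuracy or val_loss")
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y, dtype=np.float64)
        if len(x) == 0:
            raise ValueError("empty training set")
        opt = Adam(lr=learning_rate)
        rng = np.random.default_rng(self.seed if shuffle_seed is None else shuffle_seed)
        sign = 1.0 if monitor == "val_loss" else -1.0  # smaller-is-better score
        best_score, best_weights, bad_epochs = np.inf, None, 0
        for epoch in range(1, epochs + 1):
            order = rng.permutation(len(x))
            losses, hits, count = 0.0, 0, 0
            for i in range(0, len(x), batch_size):
                idx = order[i : i + batch_size]
                xb, yb = x[idx], y[idx]
                z = self.forward_logits(xb, train=True)
                p = sigmoid(z)
                losses += binary_cross_entropy(p, yb) * len(idx)
                hits += int(np.sum((p >= 0.5) == (yb >= 0.5)))
                count += len(idx)
                self._backward(((p - yb) / len(idx)).astype(np.float32))
                opt.step(self.layers)
            stats = EpochStats(epoch=epoch, loss=losses / count, accuracy=hits / count)
            if validation is not None:
                stats.val_loss, stats.val_accuracy = self.evaluate(*validation)
            self.history.append(stats)
            if stop_at_accuracy is not None and stats.accuracy >= stop_at_accuracy:
                break
            if validation is not None and patience is not None:
                score = sign * (stats.val_loss if monitor == "val_loss" else stats.val_accuracy)
                if score < best_score - min_delta:
                    best_score, bad_epochs = score, 0
                    best_weights = self.get_weights()
                else:
                    bad_epochs += 1
                    if bad_epochs >= patience:
                        break
        if best_weights is not None:
            self.set_weights(best_weights)
        return self

    # -- persistence -------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [getattr(l, n).copy() for l in self.layers for n in l.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers:
            for name in layer.params:
                cur = getattr(layer, name)
                new = next(it)
                if cur.shape != new.shape:
                    raise ValueError("weight shape mismatch")
                setattr(layer, name, new.astype(cur.dtype).copy())

    def save(self, path) -> None:
        arrays = {f"w{i}": w for i, w in enumerate(self.get_weights())}
        meta = json.dumps({"fingerprint": self.fingerprint, "seed": self.seed})
        np.savez_compressed(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    def load_weights(self, path) -> "Network":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta["fingerprint"] != self.fingerprint:
                raise ValueError(
                    f"checkpoint fingerprint {meta['fingerprint']!r} does not match "
                    f"this architecture {self.fingerprint!r}"
                )
            n = len([k for k in data.files if k.startswith("w")])
            self.set_weights([data[f"w{i}"] for i in range(n)])
        return self
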