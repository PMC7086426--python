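"""A compact numpy implementation of the convolutional classifier.

Feature maps are stored channels-last, ``(batch, h, w, depth)``.  Valid
convolutions with square kernels are evaluated as a sum of ``f*f`` strided
matrix products, which keeps memory bounded and runs through BLAS; the same
slicing pattern drives the backward pass.  Batch normalization keeps running
moments for inference; pooling is mean pooling.  Optimization is plain
stochastic gradient descent with momentum and an L2 penalty on convolution
and dense weights (not on biases or normalization parameters):

    v <- momentum * v - lr * (grad + l2 * w);    w <- w + v

All randomness (weight initialization) flows through a single
``numpy.random.Generator``, so a seed fixes the whole training trajectory.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError
from .topology import CONV, DENSE, POOL, TopologySpec, trace_shapes

_DTYPE = np.float32


class Parameter:
    """A learnable array with its gradient and weight-decay eligibility."""

    __slots__ = ("name", "value", "grad", "decay")

    def __init__(self, name: str, value: np.ndarray, decay: bool):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay


def _windows(x: np.ndarray, u: int, v: int, ho: int, wo: int, s: int) -> np.ndarray:
    """Strided view selecting window offset (u, v) for every output position."""
    return x[:, u:u + ho * s:s, v:v + wo * s:s, :]


class _ConvLayer:
    """Valid convolution via im2col: one BLAS matmul per pass."""

    def __init__(self, f: int, s: int, c_in: int, c_out: int,
                 rng: np.random.Generator, compute_dx: bool = True):
        self.f, self.s, self.c_in = f, s, c_in
        self.compute_dx = compute_dx
        std = np.sqrt(2.0 / (f * f * c_in))
        self.W = Parameter(
            "W", rng.normal(0.0, std, size=(f, f, c_in, c_out)).astype(_DTYPE),
            decay=True)
        self.b = Parameter("b", np.zeros(c_out, dtype=_DTYPE), decay=False)
        self._cols: np.ndarray | None = None
        self._in_shape = None

    def params(self):
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray, ho: int, wo: int) -> np.ndarray:
        f, s, c = self.f, self.s, self.c_in
        cols = np.empty((x.shape[0], ho, wo, f * f * c), dtype=_DTYPE)
        for u in range(f):
            for v in range(f):
                k = (u * f + v) * c
                cols[..., k:k + c] = _windows(x, u, v, ho, wo, s)
        return cols.reshape(-1, f * f * c)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        f, s = self.f, self.s
        ho = (x.shape[1] - f + s) // s
        wo = (x.shape[2] - f + s) // s
        if ho < 1 or wo < 1:
            raise ShapeError(f"input {x.shape[1:3]} smaller than kernel {f}")
        c_out = self.W.value.shape[-1]
        cols = self._im2col(x, ho, wo)
        out = cols @ self.W.value.reshape(-1, c_out) + self.b.value
        if training:
            self._cols = cols
            self._in_shape = x.shape
        return out.reshape(x.shape[0], ho, wo, c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        f, s, c = self.f, self.s, self.c_in
        ho, wo = dout.shape[1], dout.shape[2]
        c_out = dout.shape[3]
        dout2 = dout.reshape(-1, c_out)
        self.b.grad = dout2.sum(axis=0)
        self.W.grad = (self._cols.T @ dout2).reshape(self.W.value.shape)
        if not self.compute_dx:  # first layer: input gradient is never used
            self._cols = None
            self._in_shape = None
            return None
        dcols = (dout2 @ self.W.value.reshape(-1, c_out).T) \
            .reshape(dout.shape[0], ho, wo, f * f * c)
        dx = np.zeros(self._in_shape, dtype=_DTYPE)
        for u in range(f):
            for v in range(f):
                k = (u * f + v) * c
                dx[:, u:u + ho * s:s, v:v + wo * s:s, :] += dcols[..., k:k + c]
        self._cols = None
        self._in_shape = None
        return dx


class _BatchNormLayer:
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter("gamma", np.ones(c, dtype=_DTYPE), decay=False)
        self.beta = Parameter("beta", np.zeros(c, dtype=_DTYPE), decay=False)
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(c, dtype=_DTYPE)
        self.running_var = np.ones(c, dtype=_DTYPE)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if training:
            self._cache = (xhat, inv_std)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        axes = tuple(range(dout.ndim - 1))
        n = dout.size // dout.shape[-1]
        self.gamma.grad = (dout * xhat).sum(axis=axes)
        self.beta.grad = dout.sum(axis=axes)
        dx = (self.gamma.value * inv_std / n) * (
            n * dout - self.beta.grad - xhat * self.gamma.grad
        )
        self._cache = None
        return dx.astype(_DTYPE, copy=False)


class _ReLULayer:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class _AvgPoolLayer:
    def __init__(self, f: int, s: int):
        self.f, self.s = f, s
        self._in_shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        f, s = self.f, self.s
        ho = (x.shape[1] - f + s) // s
        wo = (x.shape[2] - f + s) // s
        if ho < 1 or wo < 1:
            raise ShapeError(f"input {x.shape[1:3]} smaller than window {f}")
        out = np.zeros((x.shape[0], ho, wo, x.shape[3]), dtype=_DTYPE)
        for u in range(f):
            for v in range(f):
                out += _windows(x, u, v, ho, wo, s)
        out /= f * f
        if training:
            self._in_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        f, s = self.f, self.s
        ho, wo = dout.shape[1], dout.shape[2]
        dx = np.zeros(self._in_shape, dtype=_DTYPE)
        share = dout / (f * f)
        for u in range(f):
            for v in range(f):
                dx[:, u:u + ho * s:s, v:v + wo * s:s, :] += share
        self._in_shape = None
        return dx


class _DenseLayer:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / d_in)
        self.W = Parameter("W", rng.normal(0.0, std, (d_in, d_out)).astype(_DTYPE),
                           decay=True)
        self.b = Parameter("b", np.zeros(d_out, dtype=_DTYPE), decay=False)
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        flat = x.reshape(x.shape[0], -1)
        if flat.shape[1] != self.W.value.shape[0]:
            raise ShapeError(
                f"dense layer expects {self.W.value.shape[0]} inputs, "
                f"got {flat.shape[1]}"
            )
        if training:
            self._x = flat
            self._in_shape = x.shape
        return flat @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad = self._x.T @ dout
        self.b.grad = dout.sum(axis=0)
        dx = (dout @ self.W.value.T).reshape(self._in_shape)
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """The layer stack instantiated from a :class:`TopologySpec`."""

    def __init__(self, spec: TopologySpec, rng: np.random.Generator):
        self.spec = spec
        self.layers: list = []
        shape = spec.input_shape
        shapes = trace_shapes(spec)
        for layer_spec, out_shape in zip(spec.layers, shapes):
            if layer_spec.kind == CONV:
                first = not self.layers
                self.layers.append(_ConvLayer(layer_spec.f, layer_spec.s,
                                              shape.l, layer_spec.filters, rng,
                                              compute_dx=not first))
                for op in layer_spec.post_ops:
                    if op == "batch_norm":
                        self.layers.append(_BatchNormLayer(layer_spec.filters))
                    elif op == "relu":
                        self.layers.append(_ReLULayer())
            elif layer_spec.kind == POOL:
                self.layers.append(_AvgPoolLayer(layer_spec.f, layer_spec.s))
            else:
                self.layers.append(_DenseLayer(shape.size, spec.num_classes, rng))
            shape = out_shape

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a ``(batch, h, w, 1)`` input block."""
        out = x
        for layer in self.layers:
            out = layer.forward(out, training)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        probs = []
        for start in range(0, x.shape[0], batch_size):
            logits = self.forward(x[start:start + batch_size], training=False)
            probs.append(softmax(logits))
        return np.concatenate(probs, axis=0)

    def train_step(self, x: np.ndarray, y: np.ndarray,
                   l2: float) -> tuple[float, np.ndarray]:
        """One forward/backward pass; fills gradients, returns (loss, probs).

        Loss is mean cross-entropy plus ``0.5 * l2 * sum(w^2)`` over
        decay-eligible weights; the matching ``l2 * w`` term is added to
        their gradients.
        """
        n = x.shape[0]
        logits = self.forward(x, training=True)
        probs = softmax(logits)
        ce = -np.mean(np.log(probs[np.arange(n), y] + 1e-12))
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grad = dlogits.astype(_DTYPE)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        penalty = 0.0
        for p in self.parameters():
            if p.decay:
                penalty += float(np.sum(p.value.astype(np.float64) ** 2))
                p.grad = p.grad + l2 * p.value
        return ce + 0.5 * l2 * penalty, probs

    def weight_norm(self) -> float:
        """L2 norm of all decay-eligible weights."""
        total = 0.0
        for p in self.parameters():
            if p.decay:
                total += float(np.sum(p.value.astype(np.float64) ** 2))
        return float(np.sqrt(total))


class SGDMomentum:
    """Classic momentum update: v <- m*v - lr*grad; w <- w + v."""

    def __init__(self, params: list[Parameter], learning_rate: float,
                 momentum: float):
        self.params = params
        self.lr = learning_rate
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v
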