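"""A minimal vectorized reverse-mode automatic-differentiation engine.

Just enough numpy-backed autodiff to train the convolutional-biLSTM-attention
estimator deterministically on a CPU: tensors over float64 arrays, the ops the
architecture needs (matmul, broadcast add/mul, tanh, sigmoid, softmax, concat,
slicing, mean), an LSTM cell, and Adam.  Gradients are checked against
numerical differentiation in the test suite.

Design notes: graphs are built eagerly per forward pass and freed afterwards;
constants (network inputs) are plain ndarrays and never receive gradients;
broadcasting in ``add``/``mul`` is undone in the backward pass by summing over
the broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "matmul", "add", "sub", "mul", "tanh", "sigmoid", "concat", "slice_cols",
    "softmax", "mean_all",
    "Linear", "LSTMCell", "Adam",
]

Arrayish = "Tensor | np.ndarray | float"


class Tensor:
    """A node in the autodiff graph."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = parents
        self._backward = backward  # closure(out_grad) -> accumulates into parents

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) node."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> np.ndarray:
        return self.data


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    # undo broadcasting: sum over prepended axes, then over size-1 axes
    while g.ndim > t.data.ndim:
        g = g.sum(axis=0)
    for ax, size in enumerate(t.data.shape):
        if size == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    t.grad = g if t.grad is None else t.grad + g


def _const(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def matmul(a, b: Tensor) -> Tensor:
    """``a @ b`` where ``a`` may be a constant ndarray or a Tensor."""
    a_t = a if isinstance(a, Tensor) else None
    b_t = b if isinstance(b, Tensor) else None
    a_d = a.data if a_t is not None else _const(a)
    b_d = b.data if b_t is not None else _const(b)
    parents = tuple(t for t in (a_t, b_t) if t is not None)
    out = Tensor(a_d @ b_d, parents)

    def backward(g):
        if a_t is not None:
            _accumulate(a_t, g @ b_d.T)
        if b_t is not None:
            _accumulate(b_t, a_d.T @ g)

    out._backward = backward
    return out


def _binary(a, b, fwd, bwd_a, bwd_b) -> Tensor:
    a_t = a if isinstance(a, Tensor) else None
    b_t = b if isinstance(b, Tensor) else None
    a_d = a.data if a_t is not None else _const(a)
    b_d = b.data if b_t is not None else _const(b)
    out = Tensor(fwd(a_d, b_d), tuple(t for t in (a_t, b_t) if t is not None))

    def backward(g):
        if a_t is not None:
            _accumulate(a_t, bwd_a(g, a_d, b_d))
        if b_t is not None:
            _accumulate(b_t, bwd_b(g, a_d, b_d))

    out._backward = backward
    return out


def add(a, b) -> Tensor:
    return _binary(a, b, lambda x, y: x + y, lambda g, x, y: g, lambda g, x, y: g)


def sub(a, b) -> Tensor:
    return _binary(a, b, lambda x, y: x - y, lambda g, x, y: g, lambda g, x, y: -g)


def mul(a, b) -> Tensor:
    return _binary(
        a, b, lambda x, y: x * y, lambda g, x, y: g * y, lambda g, x, y: g * x
    )


def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)
    out = Tensor(y, (a,))
    out._backward = lambda g: _accumulate(a, g * (1.0 - y * y))
    return out


def sigmoid(a: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))
    out = Tensor(y, (a,))
    out._backward = lambda g: _accumulate(a, g * y * (1.0 - y))
    return out


def concat(parts: list[Tensor], axis: int = -1) -> Tensor:
    datas = [p.data for p in parts]
    out = Tensor(np.concatenate(datas, axis=axis), tuple(parts))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for p, gp in zip(parts, np.split(g, splits, axis=axis)):
            _accumulate(p, gp)

    out._backward = backward
    return out


def slice_cols(a: Tensor, start: int, stop: int) -> Tensor:
    out = Tensor(a.data[..., start:stop], (a,))

    def backward(g):
        full = np.zeros_like(a.data)
        full[..., start:stop] = g
        _accumulate(a, full)

    out._backward = backward
    return out


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, (a,))

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        _accumulate(a, y * (g - dot))

    out._backward = backward
    return out


def mean_all(a: Tensor) -> Tensor:
    out = Tensor(a.data.mean(), (a,))
    out._backward = lambda g: _accumulate(a, np.full_like(a.data, g / a.data.size))
    return out


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------


class Linear:
    """Dense layer ``x @ W + b`` with Glorot-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.b = Tensor(np.zeros(n_out))

    def __call__(self, x) -> Tensor:
        return add(matmul(x, self.W), self.b)

    def params(self) -> list[Tensor]:
        return [self.W, self.b]


class LSTMCell:
    """Standard LSTM cell; gate order i, f, g, o along the fused weight."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        bound = np.sqrt(6.0 / (n_in + n_hidden + 4 * n_hidden))
        self.Wx = Tensor(rng.uniform(-bound, bound, size=(n_in, 4 * n_hidden)))
        self.Wh = Tensor(rng.uniform(-bound, bound, size=(n_hidden, 4 * n_hidden)))
        b = np.zeros(4 * n_hidden)
        b[n_hidden : 2 * n_hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b)

    def __call__(self, x, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        H = self.n_hidden
        z = add(add(matmul(x, self.Wx), matmul(h, self.Wh)), self.b)
        i = sigmoid(slice_cols(z, 0, H))
        f = sigmoid(slice_cols(z, H, 2 * H))
        g = tanh(slice_cols(z, 2 * H, 3 * H))
        o = sigmoid(slice_cols(z, 3 * H, 4 * H))
        c_new = add(mul(f, c), mul(i, g))
        h_new = mul(o, tanh(c_new))
        return h_new, c_new

    def params(self) -> list[Tensor]:
        return [self.Wx, self.Wh, self.b]


class Adam:
    """Adam optimizer over a flat list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-2,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * p.grad
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * p.grad**2
            m_hat = self.m[k] / (1 - self.beta1**self.t)
            v_hat = self.v[k] / (1 - self.beta2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
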