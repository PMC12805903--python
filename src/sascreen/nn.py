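"""Self-contained neural-network core: reverse-mode autodiff on numpy arrays.

Implements exactly the pieces the sequence-to-activity regressor needs —
1-D convolution ("same" padding), max-pooling, dense layers, LeakyReLU,
dropout, a bidirectional GRU with recurrent dropout, mean-squared-error loss
and the Adam optimizer.  Gradients are computed by a small tape: every op
records its parents and a closure that accumulates gradients into them.
Correctness is verified against numerical differentiation in the test suite.

Arrays are float32 by default; sequence inputs are channels-last ``(B, L, C)``.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad", "name")

    def __init__(self, data, requires_grad=False, parents=(), backward=None, name=""):
        self.data = np.asarray(data)
        self.grad = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g

    # convenience operators
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __matmul__(self, other):
        return matmul(self, other)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    out._backward = bwd
    return out


def sub(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data - b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g, b.data.shape))

    out._backward = bwd
    return out


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    out._backward = bwd
    return out


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    out._backward = bwd
    return out


def sigmoid(x):
    x = _as_tensor(x)
    y = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(y, parents=(x,))

    def bwd(g):
        x._accum(g * y * (1.0 - y))

    out._backward = bwd
    return out


def tanh(x):
    x = _as_tensor(x)
    y = np.tanh(x.data)
    out = Tensor(y, parents=(x,))

    def bwd(g):
        x._accum(g * (1.0 - y * y))

    out._backward = bwd
    return out


def leaky_relu(x, alpha=0.01):
    x = _as_tensor(x)
    pos = x.data > 0
    out = Tensor(np.where(pos, x.data, alpha * x.data), parents=(x,))

    def bwd(g):
        x._accum(g * np.where(pos, 1.0, alpha).astype(g.dtype))

    out._backward = bwd
    return out


def reshape(x, shape):
    x = _as_tensor(x)
    out = Tensor(x.data.reshape(shape), parents=(x,))

    def bwd(g):
        x._accum(g.reshape(x.data.shape))

    out._backward = bwd
    return out


def concat(tensors, axis=-1):
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def bwd(g):
        splits = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, gs in zip(tensors, splits):
            if t.requires_grad:
                t._accum(gs)

    out._backward = bwd
    return out


def slice_axis(x, axis, start, stop):
    x = _as_tensor(x)
    idx = [slice(None)] * x.data.ndim
    idx[axis] = slice(start, stop)
    idx = tuple(idx)
    out = Tensor(x.data[idx], parents=(x,))

    def bwd(g):
        full = np.zeros_like(x.data)
        full[idx] = g
        x._accum(full)

    out._backward = bwd
    return out


def flip_axis1(x):
    x = _as_tensor(x)
    out = Tensor(x.data[:, ::-1], parents=(x,))

    def bwd(g):
        x._accum(g[:, ::-1])

    out._backward = bwd
    return out


def mean(x):
    x = _as_tensor(x)
    out = Tensor(np.asarray(x.data.mean()), parents=(x,))

    def bwd(g):
        x._accum(np.full_like(x.data, g / x.data.size))

    out._backward = bwd
    return out


def mse_loss(pred, target):
    pred = _as_tensor(pred)
    target = np.asarray(target, dtype=pred.data.dtype).reshape(pred.data.shape)
    diff = sub(pred, Tensor(target))
    return mean(mul(diff, diff))


def conv1d_same(x, w, b):
    """1-D convolution with 'same' zero padding, stride 1.

    x: (B, L, C_in); w: (k, C_in, C_out); b: (C_out,).
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    B, L, C = x.data.shape
    k, _, F = w.data.shape
    pl, pr = (k - 1) // 2, k // 2
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
    # windows: (B, L, k, C)
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
    win = win.transpose(0, 1, 3, 2)
    cols = np.ascontiguousarray(win).reshape(B * L, k * C)
    wm = w.data.reshape(k * C, F)
    y = (cols @ wm + b.data).reshape(B, L, F)
    out = Tensor(y, parents=(x, w, b))

    def bwd(g):
        gm = g.reshape(B * L, F)
        if w.requires_grad:
            w._accum((cols.T @ gm).reshape(k, C, F))
        if b.requires_grad:
            b._accum(gm.sum(axis=0))
        if x.requires_grad:
            gcols = (gm @ wm.T).reshape(B, L, k, C)
            gxp = np.zeros_like(xp)
            for i in range(k):
                gxp[:, i:i + L, :] += gcols[:, :, i, :]
            x._accum(gxp[:, pl:pl + L, :])

    out._backward = bwd
    return out


def max_pool1d_same(x, size=2):
    """Max pooling along axis 1 with 'same' padding: L -> ceil(L / size)."""
    x = _as_tensor(x)
    B, L, C = x.data.shape
    Lp = -(-L // size) * size
    xp = np.pad(x.data, ((0, 0), (0, Lp - L), (0, 0)),
                constant_values=-np.inf)
    blocks = xp.reshape(B, Lp // size, size, C)
    arg = blocks.argmax(axis=2)
    y = np.take_along_axis(blocks, arg[:, :, None, :], axis=2)[:, :, 0, :]
    out = Tensor(y, parents=(x,))

    def bwd(g):
        gxp = np.zeros((B, Lp // size, size, C), dtype=g.dtype)
        np.put_along_axis(gxp, arg[:, :, None, :], g[:, :, None, :], axis=2)
        x._accum(gxp.reshape(B, Lp, C)[:, :L, :])

    out._backward = bwd
    return out


def dropout(x, rate, rng, train):
    if not train or rate <= 0.0:
        return _as_tensor(x)
    x = _as_tensor(x)
    mask = (rng.random(x.data.shape) >= rate).astype(x.data.dtype) / (1.0 - rate)
    return mul(x, Tensor(mask))


# ---------------------------------------------------------------------------
# layers


def glorot_uniform(rng, shape, fan_in, fan_out, dtype=np.float32):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def orthogonal(rng, rows, cols, dtype=np.float32):
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if rows < cols:
        q = q.T
    return np.ascontiguousarray(q[:rows, :cols]).astype(dtype)


class Dense:
    def __init__(self, rng, n_in, n_out):
        self.w = Tensor(glorot_uniform(rng, (n_in, n_out), n_in, n_out),
                        requires_grad=True, name="dense_w")
        self.b = Tensor(np.zeros(n_out, dtype=np.float32),
                        requires_grad=True, name="dense_b")

    def __call__(self, x):
        return add(matmul(x, self.w), self.b)

    def parameters(self):
        return [self.w, self.b]


class Conv1D:
    def __init__(self, rng, c_in, filters, kernel=3):
        fan_in, fan_out = kernel * c_in, kernel * filters
        self.w = Tensor(glorot_uniform(rng, (kernel, c_in, filters), fan_in, fan_out),
                        requires_grad=True, name="conv_w")
        self.b = Tensor(np.zeros(filters, dtype=np.float32),
                        requires_grad=True, name="conv_b")

    def __call__(self, x):
        return conv1d_same(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class GRU:
    """Single-direction GRU returning the final hidden state.

    Classic formulation (reset gate applied inside the candidate):
        z = sigma(x W_z + h U_z);  r = sigma(x W_r + h U_r)
        n = tanh(x W_n + r * (h U_n));  h' = z * h + (1 - z) * n
    Recurrent dropout applies one mask per sequence to the hidden state
    entering the recurrent projections.
    """

    def __init__(self, rng, c_in, units, recurrent_dropout=0.0):
        self.units = units
        self.recurrent_dropout = recurrent_dropout
        self.wx = Tensor(glorot_uniform(rng, (c_in, 3 * units), c_in, 3 * units),
                         requires_grad=True, name="gru_wx")
        u = np.concatenate([orthogonal(rng, units, units) for _ in range(3)], axis=1)
        self.u = Tensor(u, requires_grad=True, name="gru_u")
        self.b = Tensor(np.zeros(3 * units, dtype=np.float32),
                        requires_grad=True, name="gru_b")

    def __call__(self, x, rng, train):
        B, T, _ = x.data.shape
        H = self.units
        xp = add(matmul(reshape(x, (B * T, x.data.shape[2])), self.wx), self.b)
        xp = reshape(xp, (B, T, 3 * H))
        h = Tensor(np.zeros((B, H), dtype=np.float32))
        if train and self.recurrent_dropout > 0.0:
            keep = 1.0 - self.recurrent_dropout
            rmask = Tensor((rng.random((B, H)) < keep).astype(np.float32) / keep)
        else:
            rmask = None
        one = Tensor(np.float32(1.0))
        for t in range(T):
            xt = reshape(slice_axis(xp, 1, t, t + 1), (B, 3 * H))
            hd = mul(h, rmask) if rmask is not None else h
            hu = matmul(hd, self.u)
            z = sigmoid(add(slice_axis(xt, 1, 0, H), slice_axis(hu, 1, 0, H)))
            r = sigmoid(add(slice_axis(xt, 1, H, 2 * H), slice_axis(hu, 1, H, 2 * H)))
            n = tanh(add(slice_axis(xt, 1, 2 * H, 3 * H),
                         mul(r, slice_axis(hu, 1, 2 * H, 3 * H))))
            h = add(mul(z, h), mul(sub(one, z), n))
        return h

    def parameters(self):
        return [self.wx, self.u, self.b]


class BiGRU:
    """Bidirectional GRU: concatenated final states of both directions."""

    def __init__(self, rng, c_in, units, recurrent_dropout=0.0):
        self.fwd = GRU(rng, c_in, units, recurrent_dropout)
        self.bwd = GRU(rng, c_in, units, recurrent_dropout)

    def __call__(self, x, rng, train):
        hf = self.fwd(x, rng, train)
        hb = self.bwd(flip_axis1(x), rng, train)
        return concat([hf, hb], axis=1)

    def parameters(self):
        return self.fwd.parameters() + self.bwd.parameters()


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p.data -= lr_t * m / (np.sqrt(v) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
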