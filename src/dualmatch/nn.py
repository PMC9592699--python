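"""Minimal CPU autograd for small convolutional networks.

A compact reverse-mode automatic differentiation engine over numpy arrays,
sized for the desk-scale networks this package trains: dense/strided 2-D
convolution (via im2col), batch normalization with running statistics,
constant-value spatial padding, pooling, linear layers, softmax
cross-entropy, and SGD/Adam optimizers.  float32 throughout.

Only what the transfer-learning pipeline needs is implemented: no groups,
no dilation, no even kernels.
"""

from __future__ import annotations

import numpy as np

_F32 = np.float32


class Tensor:
    """A numpy array plus an accumulated gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=_F32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(_F32, copy=True)
        else:
            self.grad += g

    def backward(self):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------- basic ops

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def back(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(g, b.shape))

    out._backward = back
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = Tensor(a.data - b.data, parents=(a, b))

    def back(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(-g, b.shape))

    out._backward = back
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def back(g):
        a._accum(_unbroadcast(g * b.data, a.shape))
        b._accum(_unbroadcast(g * a.data, b.shape))

    out._backward = back
    return out


def scale(a: Tensor, s: float) -> Tensor:
    out = Tensor(a.data * s, parents=(a,))
    out._backward = lambda g: a._accum(g * s)
    return out


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def back(g):
        if axis is None:
            a._accum(np.broadcast_to(g, a.shape).astype(_F32))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.shape).astype(_F32))

    out._backward = back
    return out


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = a.data.size
    elif isinstance(axis, tuple):
        n = int(np.prod([a.data.shape[ax] for ax in axis]))
    else:
        n = a.data.shape[axis]
    return scale(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), parents=(a,))
    out._backward = lambda g: a._accum(g.reshape(a.shape))
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, parents=(a,))
    out._backward = lambda g: a._accum(g * mask)
    return out


def relu6(a: Tensor) -> Tensor:
    out_data = np.clip(a.data, 0.0, 6.0)
    mask = (a.data > 0) & (a.data < 6)
    out = Tensor(out_data, parents=(a,))
    out._backward = lambda g: a._accum(g * mask)
    return out


def softmax(a: Tensor, axis=-1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, parents=(a,))

    def back(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        a._accum(s * (g - dot))

    out._backward = back
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, parents=(a, b))

    def back(g):
        a._accum(g @ b.data.T)
        b._accum(a.data.T @ g)

    out._backward = back
    return out


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x (N, Din) @ w (Din, Dout) + b."""
    out = matmul(x, w)
    if b is not None:
        out = add(out, b)
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over the batch; labels are integer classes."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    loss = -np.log(np.maximum(p[np.arange(n), labels], 1e-12)).mean()
    out = Tensor(loss, parents=(logits,))

    def back(g):
        dp = p.copy()
        dp[np.arange(n), labels] -= 1.0
        logits._accum(g * dp / n)

    out._backward = back
    return out


# ------------------------------------------------------------- spatial ops

def pad2d(x: Tensor, p: int, value: Tensor | None = None) -> Tensor:
    """Pad H and W by ``p`` with a per-channel constant (default zero).

    ``value`` has shape (C,); its gradient is the sum of incoming gradients
    over the border positions, which is what makes bias-value padding in the
    diverse branch block differentiable.
    """
    if p == 0:
        return x
    n, c, h, w = x.shape
    out_data = np.empty((n, c, h + 2 * p, w + 2 * p), dtype=_F32)
    fill = value.data.reshape(1, c, 1, 1) if value is not None else 0.0
    out_data[...] = fill
    out_data[:, :, p:-p, p:-p] = x.data
    parents = (x, value) if value is not None else (x,)
    out = Tensor(out_data, parents=parents)

    def back(g):
        x._accum(g[:, :, p:-p, p:-p])
        if value is not None:
            border = g.sum(axis=(0, 2, 3)) - g[:, :, p:-p, p:-p].sum(axis=(0, 2, 3))
            value._accum(border)

    out._backward = back
    return out


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    n, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    return view.reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(dcols: np.ndarray, xshape, kh: int, kw: int, stride: int, ho: int, wo: int):
    n, c, h, w = xshape
    dx = np.zeros(xshape, dtype=_F32)
    d6 = dcols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d6[:, :, i, j]
    return dx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """Valid (no padding) 2-D convolution; pad with :func:`pad2d` beforehand.

    ``w`` has shape (D, C, K, K), ``b`` shape (D,).
    """
    n, c, h, wd = x.shape
    dout, cin, kh, kw = w.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, kernel {cin}")
    cols, ho, wo = _im2col(x.data, kh, kw, stride)
    wr = w.data.reshape(dout, -1)
    out_data = np.matmul(wr, cols).reshape(n, dout, ho, wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, dout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents=parents)

    def back(g):
        g2 = g.reshape(n, dout, ho * wo)
        dw = np.einsum("ndl,nkl->dk", g2, cols, optimize=True).reshape(w.shape)
        w._accum(dw)
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        dcols = np.einsum("dk,ndl->nkl", wr, g2, optimize=True)
        x._accum(_col2im(dcols, x.shape, kh, kw, stride, ho, wo))

    out._backward = back
    return out


def maxpool2d(x: Tensor, k: int, stride: int) -> Tensor:
    n, c, h, w = x.shape
    cols, ho, wo = _im2col(x.data, k, k, stride)
    cols6 = cols.reshape(n, c, k * k, ho * wo)
    arg = cols6.argmax(axis=2)
    out_data = np.take_along_axis(cols6, arg[:, :, None, :], axis=2)[:, :, 0, :]
    out = Tensor(out_data.reshape(n, c, ho, wo), parents=(x,))

    def back(g):
        dcols6 = np.zeros((n, c, k * k, ho * wo), dtype=_F32)
        np.put_along_axis(dcols6, arg[:, :, None, :], g.reshape(n, c, 1, ho * wo), axis=2)
        x._accum(_col2im(dcols6.reshape(n, c * k * k, ho * wo), x.shape, k, k, stride, ho, wo))

    out._backward = back
    return out


def global_mean_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C), the spatial mean per channel."""
    n, c, h, w = x.shape
    out = Tensor(x.data.mean(axis=(2, 3)), parents=(x,))

    def back(g):
        x._accum(np.broadcast_to(g[:, :, None, None] / (h * w), x.shape).astype(_F32))

    out._backward = back
    return out


def resize_bilinear(x: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Endpoint-aligned separable bilinear resize of a (..., H, W) array.

    Gradient-free: used only on frozen source feature maps and images.
    """
    h, w = x.shape[-2], x.shape[-1]
    rows = np.linspace(0.0, h - 1.0, out_h) if out_h > 1 else np.zeros(1)
    cols = np.linspace(0.0, w - 1.0, out_w) if out_w > 1 else np.zeros(1)
    r0 = np.floor(rows).astype(np.intp)
    r1 = np.minimum(r0 + 1, h - 1)
    fr = (rows - r0).astype(np.float32).reshape(-1, 1)
    c0 = np.floor(cols).astype(np.intp)
    c1 = np.minimum(c0 + 1, w - 1)
    fc = (cols - c0).astype(np.float32)
    # separable: rows first, then columns
    xr = x.take(r0, axis=-2) * (1 - fr) + x.take(r1, axis=-2) * fr
    out = xr.take(c0, axis=-1) * (1 - fc) + xr.take(c1, axis=-1) * fc
    return out.astype(x.dtype)


# ----------------------------------------------------------------- layers

class Module:
    """Base class: parameter discovery by attribute walk."""

    def params(self):
        out = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def zero_grad(self):
        for p in self.params():
            p.zero_grad()

    def state_arrays(self):
        """Flat list of all arrays (parameters + buffers) for (de)serialization."""
        out = []
        for v in vars(self).values():
            if isinstance(v, Tensor):
                out.append(v.data)
            elif isinstance(v, np.ndarray):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.state_arrays())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.state_arrays())
        return out


class Conv2d(Module):
    """Plain convolution with same-style zero padding (K odd)."""

    def __init__(self, cin, cout, k, stride=1, rng=None, bias=True):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.weight = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.k, self.stride, self.pad = k, stride, (k - 1) // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(pad2d(x, self.pad), self.weight, self.bias, stride=self.stride)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=_F32)
        self.running_var = np.ones(c, dtype=_F32)
        self.momentum, self.eps = momentum, eps
        self._last_mean = self.running_mean
        self._last_var = self.running_var

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(_F32)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(_F32)
        else:
            mean, var = self.running_mean, self.running_var
        self._last_mean, self._last_var = mean, var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
        out_data = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        out = Tensor(out_data, parents=(x, self.gamma, self.beta))
        n_el = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

        def back(g):
            self.beta._accum(g.sum(axis=(0, 2, 3)))
            self.gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            gx = g * self.gamma.data[None, :, None, None]
            if training:
                # full batch-stat backward
                sum_gx = gx.sum(axis=(0, 2, 3), keepdims=True)
                sum_gx_xhat = (gx * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (gx - sum_gx / n_el - xhat * sum_gx_xhat / n_el) * inv[None, :, None, None]
            else:
                dx = gx * inv[None, :, None, None]
            x._accum(dx.astype(_F32))

        out._backward = back
        return out

    def bias_at_zero(self) -> Tensor:
        """BN output for a zero input under running stats: beta - mu*gamma/sigma.

        Used as the padding value that makes DBB branch merging exact at
        borders (evaluation mode)."""
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        const = Tensor(-self.running_mean * inv)
        # differentiable in gamma/beta
        return add(mul(self.gamma, const), self.beta)


class Linear(Module):
    def __init__(self, din, dout, rng=None, zero_init=False):
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((din, dout))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / din), size=(din, dout))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(dout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return linear(x, self.weight, self.bias)


# -------------------------------------------------------------- optimizers

class SGD:
    def __init__(self, params, lr, momentum=0.0, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class Adam:
    def __init__(self, params, lr, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
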