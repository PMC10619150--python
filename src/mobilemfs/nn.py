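"""Compact reverse-mode autodiff engine on NumPy arrays.

Everything in this package that learns — attention gates, bottleneck blocks,
the full classifier — is expressed in terms of the :class:`Tensor` type defined
here.  The engine is deliberately small: a tape of parent links plus a backward
closure per operation, with NCHW layout for feature maps and float32 storage
throughout.  Convolutions run through im2col + one GEMM (dense) or a
shift-accumulate loop over kernel offsets (depthwise), both with hand-written
adjoints.  Intermediate tensors keep their gradients after ``backward()``,
which is what Grad-CAM needs.
"""
from __future__ import annotations

import math
from contextlib import contextmanager
from typing import Iterable, Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


class MacTally:
    """Collects multiply-accumulate counts during an instrumented forward pass.

    Convention: one MAC counted once; normalization, activation and elementwise
    ops excluded.  Counts scale with the batch, so callers use batch size 1.
    """

    def __init__(self):
        self.total = 0
        self.records: list[dict] = []

    def record(self, kind: str, macs: int, params: int, out_shape) -> None:
        self.total += macs
        self.records.append({"kind": kind, "macs": macs, "params": params,
                             "out_shape": tuple(out_shape)})


_TALLY_STACK: list[MacTally] = []


@contextmanager
def mac_tally() -> Iterator[MacTally]:
    t = MacTally()
    _TALLY_STACK.append(t)
    try:
        yield t
    finally:
        _TALLY_STACK.pop()


@contextmanager
def no_grad():
    """Disable graph construction (inference / statistics passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _as_f32(a) -> np.ndarray:
    arr = np.asarray(a, dtype=np.float32)
    return arr


class Tensor:
    """An n-d array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float32)  # owned copy
        else:
            self.grad += g

    def _accum_own(self, g: np.ndarray) -> None:
        """Like _accum but takes ownership of ``g`` (caller guarantees it is
        freshly allocated and not aliased elsewhere)."""
        if self.grad is None:
            self.grad = g
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        self._accum(_as_f32(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# --------------------------------------------------------------------------
# elementwise / reduction primitives
# --------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        if a.requires_grad:
            a._accum_own(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum_own(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accum_own(g * mask)

    return _make(np.where(mask, x.data, 0.0), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accum_own(g * s * (1.0 - s))

    return _make(s, (x,), backward)


def hardsigmoid(x: Tensor) -> Tensor:
    """Piecewise-linear sigmoid: clip(x/6 + 1/2, 0, 1)."""
    out = np.clip(x.data / 6.0 + 0.5, 0.0, 1.0)
    mask = (x.data > -3.0) & (x.data < 3.0)

    def backward(g):
        x._accum_own(g * mask / 6.0)

    return _make(out, (x,), backward)


def hardswish(x: Tensor) -> Tensor:
    """x * hardsigmoid(x), the MobileNet v3 activation."""
    d = x.data
    out = d * np.clip(d / 6.0 + 0.5, 0.0, 1.0)
    grad = np.where(d <= -3.0, 0.0, np.where(d >= 3.0, 1.0, d / 3.0 + 0.5))

    def backward(g):
        x._accum_own(g * grad)

    return _make(out, (x,), backward)


def mean(x: Tensor, axis, keepdims: bool = True) -> Tensor:
    axis = tuple(axis) if isinstance(axis, (tuple, list)) else (axis,)
    out = x.data.mean(axis=axis, keepdims=keepdims)
    n = int(np.prod([x.data.shape[a] for a in axis]))

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        x._accum_own(np.broadcast_to(g / n, x.data.shape).copy())

    return _make(out, (x,), backward)


def amax(x: Tensor, axis: int, keepdims: bool = True) -> Tensor:
    """Max over one axis; the gradient is routed to the (first) argmax."""
    idx = x.data.argmax(axis=axis, keepdims=True)
    out = np.take_along_axis(x.data, idx, axis=axis)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, idx, g, axis=axis)
        x._accum_own(gx)

    return _make(out if keepdims else out.squeeze(axis), (x,), backward)


def channel_max(x: Tensor) -> Tensor:
    """Max over the channel axis of an NCHW tensor, keepdims."""
    return amax(x, axis=1, keepdims=True)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(int(lo), int(hi))
                t._accum(g[tuple(sl)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    sl = [slice(None)] * x.data.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[sl] = g
        x._accum_own(gx)

    return _make(x.data[sl], (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    old = x.data.shape

    def backward(g):
        x._accum(g.reshape(old))

    return _make(x.data.reshape(shape), (x,), backward)


def transpose(x: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)

    def backward(g):
        x._accum(g.transpose(inv))

    return _make(x.data.transpose(axes), (x,), backward)


# --------------------------------------------------------------------------
# convolution / linear primitives
# --------------------------------------------------------------------------

def _conv_out_size(h: int, k: int, s: int, p: int) -> int:
    return (h + 2 * p - k) // s + 1


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-d cross-correlation, NCHW.  ``w`` is (Cout, Cin/groups, k, k).

    Supports dense convolution (groups=1) and depthwise (groups == Cin == Cout);
    those are the only group patterns the model family uses.
    """
    n, cin, h, wd = x.data.shape
    cout, cin_g, kh, kw = w.data.shape
    if kh != kw:
        raise ValueError("only square kernels are supported")
    k, s, p = kh, stride, padding
    ho, wo = _conv_out_size(h, k, s, p), _conv_out_size(wd, k, s, p)
    if groups == 1:
        if cin_g != cin:
            raise ValueError(f"weight expects {cin_g} input channels, got {cin}")
        if k == 1 and s == 1 and p == 0:
            return _conv1x1(x, w, b)
        return _conv_dense(x, w, b, k, s, p, ho, wo)
    if groups == cin == cout and cin_g == 1:
        return _conv_depthwise(x, w, b, k, s, p, ho, wo)
    raise NotImplementedError("unsupported group pattern")


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    n, cin, h, wd = x.data.shape
    cout = w.data.shape[0]
    wm = w.data.reshape(cout, cin)
    xm = x.data.reshape(n, cin, h * wd)
    out = np.einsum("oc,ncl->nol", wm, xm, optimize=True).reshape(n, cout, h, wd)
    if b is not None:
        out = out + b.data.reshape(1, cout, 1, 1)

    def backward(g):
        gm = g.reshape(n, cout, h * wd)
        if x.requires_grad:
            x._accum_own(np.einsum("oc,nol->ncl", wm, gm, optimize=True)
                         .reshape(x.data.shape))
        if w.requires_grad:
            w._accum_own(np.einsum("nol,ncl->oc", gm, xm, optimize=True)
                         .reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum_own(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def _conv_dense(x: Tensor, w: Tensor, b: Tensor | None,
                k: int, s: int, p: int, ho: int, wo: int) -> Tensor:
    n, cin, h, wd = x.data.shape
    cout = w.data.shape[0]
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)) \
        .reshape(n * ho * wo, cin * k * k)
    wm = w.data.reshape(cout, cin * k * k)
    out = (cols @ wm.T).reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data.reshape(1, cout, 1, 1)
    out = np.ascontiguousarray(out)

    def backward(g):
        gm = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        if w.requires_grad:
            w._accum_own((gm.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum_own(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = (gm @ wm).reshape(n, ho, wo, cin, k, k).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[..., i, j]
            x._accum_own(dxp[:, :, p:p + h, p:p + wd] if p else dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def _conv_depthwise(x: Tensor, w: Tensor, b: Tensor | None,
                    k: int, s: int, p: int, ho: int, wo: int) -> Tensor:
    n, c, h, wd = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    out = np.zeros((n, c, ho, wo), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            out += xp[:, :, i:i + s * ho:s, j:j + s * wo:s] \
                * w.data[:, 0, i, j][None, :, None, None]
    if b is not None:
        out += b.data.reshape(1, c, 1, 1)

    def backward(g):
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for i in range(k):
                for j in range(k):
                    gw[:, 0, i, j] = np.einsum(
                        "nchw,nchw->c", g,
                        xp[:, :, i:i + s * ho:s, j:j + s * wo:s], optimize=True)
            w._accum_own(gw)
        if b is not None and b.requires_grad:
            b._accum_own(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += \
                        g * w.data[:, 0, i, j][None, :, None, None]
            x._accum_own(dxp[:, :, p:p + h, p:p + wd] if p else dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def multi_conv2d(x: Tensor, weights: list[Tensor],
                 biases: list[Tensor | None], kernel_sizes: list[int]) -> Tensor:
    """Parallel same-padding stride-1 convolutions sharing one im2col.

    All branches read the same input; their kernels are embedded centered in
    a k_max x k_max frame so a single GEMM produces the channel-concatenated
    output (N, sum(Cb), H, W).  Numerically identical to running the branches
    separately, but one window extraction and one GEMM instead of four.
    """
    n, cin, h, wd = x.data.shape
    kmax = max(kernel_sizes)
    p = kmax // 2
    couts = [w.data.shape[0] for w in weights]
    ctot = sum(couts)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (kmax, kmax), axis=(2, 3))
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)) \
        .reshape(n * h * wd, cin * kmax * kmax)
    wbig = np.zeros((ctot, cin, kmax, kmax), dtype=np.float32)
    off = 0
    for w, k in zip(weights, kernel_sizes):
        lo = (kmax - k) // 2
        wbig[off:off + w.data.shape[0], :, lo:lo + k, lo:lo + k] = w.data
        off += w.data.shape[0]
    wm = wbig.reshape(ctot, -1)
    out = (cols @ wm.T).reshape(n, h, wd, ctot).transpose(0, 3, 1, 2)
    bias_full = None
    if any(b is not None for b in biases):
        bias_full = np.concatenate(
            [b.data if b is not None else np.zeros(c, dtype=np.float32)
             for b, c in zip(biases, couts)])
        out = out + bias_full[None, :, None, None]
    out = np.ascontiguousarray(out)

    def backward(g):
        gm = g.transpose(0, 2, 3, 1).reshape(n * h * wd, ctot)
        if any(w.requires_grad for w in weights):
            dwbig = (gm.T @ cols).reshape(ctot, cin, kmax, kmax)
            off2 = 0
            for w, k in zip(weights, kernel_sizes):
                c = w.data.shape[0]
                if w.requires_grad:
                    lo = (kmax - k) // 2
                    w._accum_own(dwbig[off2:off2 + c, :, lo:lo + k, lo:lo + k])
                off2 += c
        off2 = 0
        for b, c in zip(biases, couts):
            if b is not None and b.requires_grad:
                b._accum_own(g[:, off2:off2 + c].sum(axis=(0, 2, 3)))
            off2 += c
        if x.requires_grad:
            dcols = (gm @ wm).reshape(n, h, wd, cin, kmax, kmax) \
                .transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for i in range(kmax):
                for j in range(kmax):
                    dxp[:, :, i:i + h, j:j + wd] += dcols[..., i, j]
            x._accum_own(dxp[:, :, p:p + h, p:p + wd])

    parents = tuple([x] + list(weights) + [b for b in biases if b is not None])
    return _make(out, parents, backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x (N, Cin) @ w (Cout, Cin).T + b."""
    out = x.data @ w.data.T
    if b is not None:
        out = out + b.data

    def backward(g):
        if x.requires_grad:
            x._accum_own(g @ w.data)
        if w.requires_grad:
            w._accum_own(g.T @ x.data)
        if b is not None and b.requires_grad:
            b._accum_own(g.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def batchnorm2d(x: Tensor, weight: Tensor, bias: Tensor,
                running_mean: np.ndarray, running_var: np.ndarray, *,
                training: bool, momentum: float = 0.01,
                eps: float = 1e-3) -> Tensor:
    """Per-channel batch normalization on NCHW with affine parameters.

    In training mode the batch statistics are used and the running buffers
    updated in place; in eval mode the running buffers are used.
    """
    n, c, h, wd = x.data.shape
    m = n * h * wd
    if training:
        # single-pass sums keep this cheap on large maps
        s1 = np.einsum("nchw->c", x.data, optimize=True)
        s2 = np.einsum("nchw,nchw->c", x.data, x.data, optimize=True)
        mu = s1 / m
        var = np.maximum(s2 / m - mu * mu, 0.0)
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        # unbiased variance in the running buffer, as is conventional
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    xhat = (x.data - mu[None, :, None, None].astype(np.float32)) \
        * inv[None, :, None, None]
    out = xhat * weight.data[None, :, None, None] + bias.data[None, :, None, None]

    def backward(g):
        gsum = np.einsum("nchw->c", g, optimize=True)
        gxhat_sum = np.einsum("nchw,nchw->c", g, xhat, optimize=True)
        if bias.requires_grad:
            bias._accum_own(gsum.astype(np.float32))
        if weight.requires_grad:
            weight._accum_own(gxhat_sum.astype(np.float32))
        if x.requires_grad:
            winv = (weight.data * inv)[None, :, None, None]
            if training:
                a = (gsum / m).astype(np.float32)[None, :, None, None]
                bcoef = (gxhat_sum / m).astype(np.float32)[None, :, None, None]
                x._accum_own(winv * (g - a - xhat * bcoef))
            else:
                x._accum_own(g * winv)

    return _make(out, (x, weight, bias), backward)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over a batch of integer labels."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    nll = -np.log(np.maximum(probs[np.arange(n), labels], 1e-12)).mean()

    def backward(g):
        gp = probs.copy()
        gp[np.arange(n), labels] -= 1.0
        logits._accum_own(g * gp / n)

    return _make(np.float32(nll), (logits,), backward)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


# --------------------------------------------------------------------------
# modules
# --------------------------------------------------------------------------

class Parameter(Tensor):
    """A leaf tensor updated by an optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: attribute-walking parameter collection and train/eval mode."""

    def __init__(self):
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray],
                        strict: bool = True) -> dict[str, list[str]]:
        """Load matching name+shape entries; returns {"loaded": [...], "skipped": [...]}."""
        loaded, skipped = [], []
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, arr in state.items():
            target = params.get(name)
            if target is not None:
                if target.data.shape == arr.shape:
                    target.data = _as_f32(arr).copy()
                    loaded.append(name)
                else:
                    skipped.append(name)
                continue
            if name in buffers:
                if buffers[name].shape == arr.shape:
                    buffers[name][...] = arr
                    loaded.append(name)
                else:
                    skipped.append(name)
                continue
            skipped.append(name)
        if strict and skipped:
            raise KeyError(f"state entries not loadable: {skipped[:5]}...")
        return {"loaded": loaded, "skipped": skipped}


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, *,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        self.weight = Parameter(_kaiming(
            rng, (out_channels, in_channels // groups, kernel_size, kernel_size),
            fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.weight, self.bias, stride=self.stride,
                     padding=self.padding, groups=self.groups)
        if _TALLY_STACK:
            n = x.data.shape[0]
            macs, _ = self.mac_count(x.data.shape[2:])
            nparams = self.weight.data.size + (self.bias.data.size if self.bias is not None else 0)
            _TALLY_STACK[-1].record(
                f"conv{self.kernel_size}x{self.kernel_size}"
                + ("dw" if self.groups > 1 else ""),
                n * macs, nparams, out.data.shape)
        return out

    def mac_count(self, in_hw: tuple[int, int]) -> tuple[int, tuple[int, int]]:
        ho = _conv_out_size(in_hw[0], self.kernel_size, self.stride, self.padding)
        wo = _conv_out_size(in_hw[1], self.kernel_size, self.stride, self.padding)
        macs = ho * wo * self.out_channels * (self.in_channels // self.groups) \
            * self.kernel_size ** 2
        return macs, (ho, wo)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, *, momentum: float = 0.1,
                 eps: float = 1e-3):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return batchnorm2d(x, self.weight, self.bias, self.running_mean,
                           self.running_var, training=self.training,
                           momentum=self.momentum, eps=self.eps)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_kaiming(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = linear(x, self.weight, self.bias)
        if _TALLY_STACK:
            nparams = self.weight.data.size + (self.bias.data.size if self.bias is not None else 0)
            _TALLY_STACK[-1].record(
                "linear", x.data.shape[0] * self.mac_count(), nparams,
                out.data.shape)
        return out

    def mac_count(self) -> int:
        return self.in_features * self.out_features


class _Activation(Module):
    _fn = staticmethod(relu)

    def forward(self, x: Tensor) -> Tensor:
        return type(self)._fn(x)


class ReLU(_Activation):
    _fn = staticmethod(relu)


class HardSwish(_Activation):
    _fn = staticmethod(hardswish)


class HardSigmoid(_Activation):
    _fn = staticmethod(hardsigmoid)


class Sigmoid(_Activation):
    _fn = staticmethod(sigmoid)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Dropout(Module):
    def __init__(self, p: float = 0.2, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return mul(x, Tensor(mask.astype(np.float32)))


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    def __iter__(self):
        return iter(self.layers)


class GlobalAvgPool(Module):
    """NCHW -> NC11 spatial mean."""

    def forward(self, x: Tensor) -> Tensor:
        return mean(x, axis=(2, 3), keepdims=True)


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return reshape(x, (x.data.shape[0], -1))


# --------------------------------------------------------------------------
# optimizers
# --------------------------------------------------------------------------

class Optimizer:
    def __init__(self, params: Iterable[Parameter], lr: float):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:  # pragma: no cover - abstract
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params, lr: float = 1e-2, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        super().__init__(params, lr)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v


class Adam(Optimizer):
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        super().__init__(params, lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        bc1 = 1.0 - self.b1 ** self._t
        bc2 = 1.0 - self.b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
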