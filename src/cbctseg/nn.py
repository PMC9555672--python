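"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The segmentation network and its training loop are built on this small
engine: a :class:`Tensor` wraps an ``ndarray`` and records the backward
closure of the operation that produced it; :meth:`Tensor.backward` runs
the tape in reverse topological order.  Only the operations the network
needs exist — dense/batched matmul, layer and instance normalization,
softmax attention pieces, GELU/ReLU, 3-D convolution (stride 1) and
transposed convolution (kernel 2, stride 2), dropout, and fused losses.

All floating data is float32; gradients accumulate in float32 as well.
Gradient correctness of every primitive is established by central
finite differences in the test-suite.
"""

from __future__ import annotations

import contextlib
import math

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "no_grad",
    "concat",
    "cross_entropy_loss",
    "soft_dice_loss",
    "Adam",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing -------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        grad = np.asarray(grad, dtype=np.float32)
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
            # release graph memory as we go
            node._backward = None
            node._parents = ()

    # -- basic arithmetic ----------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._result(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._result(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (other * -1.0)

    def __rsub__(self, other):
        return Tensor(other) + (self * -1.0)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data * other.data), other.data.shape)
                )

        return Tensor._result(self.data / other.data, (self, other), backward)

    def pow(self, exponent: float):
        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._result(self.data ** exponent, (self,), backward)

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._result(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._result(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(np.ascontiguousarray(g.transpose(inv)))

        return Tensor._result(np.ascontiguousarray(self.data.transpose(axes)), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        return Tensor._result(self.data[idx], (self,), backward)

    # -- linear algebra -------------------------------------------------
    def matmul(self, other: "Tensor"):
        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._result(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- nonlinearities -------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._result(self.data * mask, (self,), backward)

    def gelu(self):
        # tanh approximation of GELU
        c = math.sqrt(2.0 / math.pi)
        x = self.data
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out = 0.5 * x * (1.0 + t)

        def backward(g):
            dinner = c * (1.0 + 3 * 0.044715 * x**2)
            grad = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner
            self._accum(g * grad)

        return Tensor._result(out, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum(s * (g - dot))

        return Tensor._result(s, (self,), backward)

    def dropout(self, rate: float, rng: np.random.Generator, training: bool):
        if not training or rate <= 0.0:
            return self
        mask = (rng.random(self.data.shape) >= rate).astype(np.float32) / (1.0 - rate)

        def backward(g):
            self._accum(g * mask)

        return Tensor._result(self.data * mask, (self,), backward)


class Parameter(Tensor):
    """A learnable tensor (``requires_grad=True``)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(np.ascontiguousarray(g[tuple(idx)]))

    return Tensor._result(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


# -- normalization ------------------------------------------------------

def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = xhat * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad:
            red = tuple(range(g.ndim - 1))
            gamma._accum((g * xhat).sum(axis=red))
            beta._accum(g.sum(axis=red))
        if x.requires_grad:
            gh = g * gamma.data
            m1 = gh.mean(axis=-1, keepdims=True)
            m2 = (gh * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv * (gh - m1 - xhat * m2))

    return Tensor._result(out, (x, gamma, beta), backward)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each (sample, channel) over its spatial extent.

    ``x`` has channels-last shape (B, *spatial, C); ``gamma``/``beta``
    have shape (C,) and broadcast over the trailing axis.
    """
    sp = tuple(range(1, x.data.ndim - 1))
    mu = x.data.mean(axis=sp, keepdims=True)
    var = x.data.var(axis=sp, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = xhat * gamma.data + beta.data

    def backward(g):
        red = (0,) + sp
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=red))
            beta._accum(g.sum(axis=red))
        if x.requires_grad:
            gh = g * gamma.data
            m1 = gh.mean(axis=sp, keepdims=True)
            m2 = (gh * xhat).mean(axis=sp, keepdims=True)
            x._accum(inv * (gh - m1 - xhat * m2))

    return Tensor._result(out, (x, gamma, beta), backward)


# -- 3-D convolutions (channels-last) -----------------------------------

def conv3d(x: Tensor, weight: Tensor, bias: Tensor, padding: int = 1) -> Tensor:
    """3-D convolution, stride 1, channels-last.

    ``x``: (B, D, H, W, Cin); ``weight``: (k, k, k, Cin, Cout);
    ``padding`` zero-pads all spatial faces.  Implemented as a sum of
    shifted channel-mixing matmuls (one BLAS call per kernel offset),
    which keeps peak memory at one padded copy of the input.
    """
    B, D, H, W, Cin = x.data.shape
    kd, kh, kw, _, Cout = weight.data.shape
    p = padding
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p), (0, 0))) if p else x.data
    Do, Ho, Wo = D + 2 * p - kd + 1, H + 2 * p - kh + 1, W + 2 * p - kw + 1
    w = weight.data
    if Cin == 1 and kd * kh * kw > 1:
        # single-channel input: per-sample im2col turns 27 rank-1 updates
        # into one well-shaped gemm
        from numpy.lib.stride_tricks import sliding_window_view

        wmat = w.reshape(kd * kh * kw, Cout)
        out = np.empty((B, Do, Ho, Wo, Cout), dtype=np.float32)
        for bi in range(B):
            sw = sliding_window_view(xp[bi, ..., 0], (kd, kh, kw))
            cols = np.ascontiguousarray(sw).reshape(-1, kd * kh * kw)
            out[bi] = (cols @ wmat).reshape(Do, Ho, Wo, Cout)
        out += bias.data
    else:
        out = np.empty((B, Do, Ho, Wo, Cout), dtype=np.float32)
        out[:] = bias.data
        for a in range(kd):
            for b in range(kh):
                for c in range(kw):
                    sl = xp[:, a : a + Do, b : b + Ho, c : c + Wo, :]
                    out += sl @ w[a, b, c]

    def backward(g):
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 1, 2, 3)))
        if weight.requires_grad:
            gw = np.empty_like(w)
            gflat = g.reshape(-1, Cout)
            for a in range(kd):
                for b in range(kh):
                    for c in range(kw):
                        sl = xp[:, a : a + Do, b : b + Ho, c : c + Wo, :]
                        gw[a, b, c] = sl.reshape(-1, Cin).T @ gflat
            weight._accum(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for a in range(kd):
                for b in range(kh):
                    for c in range(kw):
                        gxp[:, a : a + Do, b : b + Ho, c : c + Wo, :] += g @ w[a, b, c].T
            if p:
                gxp = np.ascontiguousarray(gxp[:, p:-p, p:-p, p:-p, :])
            x._accum(gxp)

    return Tensor._result(out, (x, weight, bias), backward)


def conv_transpose3d_2x(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Transposed 3-D convolution, kernel 2, stride 2, channels-last.

    ``x``: (B, D, H, W, Cin); ``weight``: (Cin, 2, 2, 2, Cout); output
    (B, 2D, 2H, 2W, Cout).  With stride == kernel the output windows do
    not overlap, so this is a single tensordot plus an interleaving
    reshape.
    """
    B, D, H, W, Cin = x.data.shape
    Cout = weight.data.shape[-1]
    t = np.tensordot(x.data, weight.data, axes=([4], [0]))  # (B,D,H,W,2,2,2,Cout)
    y = t.transpose(0, 1, 4, 2, 5, 3, 6, 7).reshape(B, 2 * D, 2 * H, 2 * W, Cout)
    y = y + bias.data

    def backward(g):
        gt = np.ascontiguousarray(
            g.reshape(B, D, 2, H, 2, W, 2, Cout).transpose(0, 1, 3, 5, 2, 4, 6, 7)
        )  # (B,D,H,W,2,2,2,Cout)
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 1, 2, 3)))
        if weight.requires_grad:
            gw = np.tensordot(x.data, gt, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
            weight._accum(gw)  # (Cin, 2, 2, 2, Cout)
        if x.requires_grad:
            gx = np.tensordot(gt, weight.data, axes=([4, 5, 6, 7], [1, 2, 3, 4]))
            x._accum(gx)

    return Tensor._result(np.ascontiguousarray(y), (x, weight, bias), backward)


# -- fused losses -------------------------------------------------------

def cross_entropy_loss(
    logits: Tensor, targets: np.ndarray, class_weights: np.ndarray | None = None
) -> Tensor:
    """Mean weighted negative log-likelihood over voxels.

    ``logits``: (N, C) raw class scores; ``targets``: (N,) integer class
    indices; ``class_weights``: (C,) nonnegative, default all ones.  The
    per-voxel term is ``-w[y_n] * log softmax(x_n)[y_n]``; the loss is the
    plain mean of those terms (so scaling all weights scales the loss).
    """
    targets = np.asarray(targets).reshape(-1).astype(np.intp)
    x = logits.data.reshape(targets.size, -1)
    C = x.shape[1]
    w = np.ones(C, dtype=np.float32) if class_weights is None else np.asarray(
        class_weights, dtype=np.float32
    )
    z = x - x.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    n = targets.size
    wy = w[targets]
    loss = -(wy * logp[np.arange(n), targets]).sum() / n

    def backward(g):
        soft = np.exp(logp)
        grad = soft * wy[:, None]
        grad[np.arange(n), targets] -= wy
        logits._accum((g * grad / n).reshape(logits.data.shape))

    return Tensor._result(np.float32(loss), (logits,), backward)


def soft_dice_loss(p: Tensor, g: np.ndarray, eps: float = 1e-5, batched: bool = False) -> Tensor:
    """Soft Dice loss ``1 - (2 Σ p_i g_i + ε) / (Σ p_i² + Σ g_i² + ε)``.

    ``p`` holds predicted foreground probabilities, ``g`` the binary
    ground truth; the smoothing ε in numerator and denominator keeps the
    loss defined on all-background crops.  With ``batched=True`` axis 0
    indexes samples and the per-sample losses are averaged.
    """
    garr = np.asarray(g, dtype=np.float32)
    pd = p.data
    if not batched:
        pd = pd.reshape(1, -1)
        garr = garr.reshape(1, -1)
    B = pd.shape[0]
    ax = tuple(range(1, pd.ndim))
    shp = (B,) + (1,) * (pd.ndim - 1)
    inter = (pd * garr).sum(axis=ax).reshape(shp)
    denom = ((pd * pd).sum(axis=ax) + (garr * garr).sum(axis=ax)).reshape(shp) + eps
    num = 2.0 * inter + eps
    loss = float(np.mean(1.0 - num / denom))

    def backward(gr):
        grad = -(2.0 * garr * denom - num * 2.0 * pd) / (denom * denom) / B
        p._accum((gr * grad).reshape(p.data.shape))

    return Tensor._result(np.float32(loss), (p,), backward)


# -- optimizer ----------------------------------------------------------

class Adam:
    """Adam with L2 weight decay added to the gradient.

    Defaults follow the common (β1, β2, ε) = (0.9, 0.999, 1e-8).
    """

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * (g * g)
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
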