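"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the heart-sound network needs:
broadcast arithmetic, (batched) matmul, 3x3/1x1 convolution, 2x2 max
pooling, batch/layer normalisation, ReLU/sigmoid/softmax, reductions and
shape ops.  Gradients accumulate into ``Tensor.grad`` on ``backward()``;
the graph is a DAG walked once in reverse topological order.

All parameters and activations are float32; gradient formulas are the
standard closed forms (verified against central finite differences in the
test suite).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum-reduce ``grad`` so it matches ``shape`` (inverse of broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _make(data, parents, backward_fn):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward_fn
        return out

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g.astype(np.float32, copy=False)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative DFS; nodes append on exit, giving reverse topological
        # order when the list is walked backwards
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        topo: list[Tensor] = []
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- basic properties -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __sub__(self, other):
        other = Tensor._coerce(other)

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(-g, other.data.shape))

        return Tensor._make(self.data - other.data, (self, other), bwd)

    def __rsub__(self, other):
        return Tensor._coerce(other) - self

    def __mul__(self, other):
        other = Tensor._coerce(other)

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __truediv__(self, other):
        other = Tensor._coerce(other)

        def bwd(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
            )

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        a, b = self.data, other.data

        def bwd(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(a @ b, (self, other), bwd)

    def __pow__(self, p: float):
        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), bwd)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(*inv))

        return Tensor._make(self.data.transpose(*axes), (self,), bwd)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g):
            if axis is None:
                self._accum(np.full_like(self.data, 1.0) * g)
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accum(g * y * (1.0 - y))

        return Tensor._make(y, (self,), bwd)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accum(y * (g - dot))

        return Tensor._make(y, (self,), bwd)

    # -- normalisation ----------------------------------------------------
    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalise over the last axis; gamma/beta are 1-D of that size."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        D = x.shape[-1]

        def bwd(g):
            gxhat = g * gamma.data
            gsum = gxhat.sum(axis=-1, keepdims=True)
            gdot = (gxhat * xhat).sum(axis=-1, keepdims=True)
            gx = inv * (gxhat - gsum / D - xhat * gdot / D)
            self._accum(gx.astype(np.float32))
            gamma._accum(
                _unbroadcast(g * xhat, gamma.data.shape)
            )
            beta._accum(_unbroadcast(g, beta.data.shape))

        return Tensor._make(xhat * gamma.data + beta.data, (self, gamma, beta), bwd)


class Parameter(Tensor):
    """A trainable tensor (requires_grad is always on)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# convolution / pooling (NCHW layout)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, H, W, C*kh*kw) patch matrix for stride-1 conv."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    # win: (N, C, H, W, kh, kw) -> (N, H, W, C, kh, kw)
    win = win.transpose(0, 2, 3, 1, 4, 5)
    n, h, w = win.shape[:3]
    return np.ascontiguousarray(win).reshape(n, h, w, -1)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Stride-1 'same' 2-D convolution (cross-correlation), square kernel.

    x: (N,Cin,H,W); weight: (Cout,Cin,k,k); bias: (Cout,).
    """
    w = weight.data
    cout, cin, kh, kw = w.shape
    pad = kh // 2
    cols = _im2col(x.data, kh, kw, pad)  # (N,H,W,cin*k*k)
    n, h, wdt, _ = cols.shape
    out = cols @ w.reshape(cout, -1).T + bias.data  # (N,H,W,cout)
    out = out.transpose(0, 3, 1, 2)

    def bwd(g):
        gflat = g.transpose(0, 2, 3, 1).reshape(-1, cout)  # (N*H*W, cout)
        if weight.requires_grad:
            gw = gflat.T @ cols.reshape(-1, cols.shape[-1])
            weight._accum(gw.reshape(w.shape))
            bias._accum(gflat.sum(axis=0))
        if x.requires_grad:
            # grad wrt input = full correlation with the flipped kernel
            wflip = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (cin,cout,k,k)
            gcols = _im2col(g, kh, kw, pad)
            gx = gcols @ wflip.reshape(cin, -1).T
            x._accum(gx.transpose(0, 3, 1, 2))

    return Tensor._make(out, (x, weight, bias), bwd)


def max_pool2x2(x: Tensor) -> Tensor:
    """2x2 stride-2 max pooling; H and W must be even."""
    n, c, h, w = x.data.shape
    assert h % 2 == 0 and w % 2 == 0, "max_pool2x2 needs even spatial dims"
    # window-last layout (N, C, H/2, W/2, 2, 2)
    v = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    out = v.max(axis=(4, 5))

    def bwd(g):
        flat = (v == out[..., None, None]).reshape(n, c, h // 2, w // 2, 4)
        # break ties: keep only the first max in each window
        first = np.cumsum(flat, axis=-1) == 1
        mask = (flat & first).reshape(n, c, h // 2, w // 2, 2, 2)
        gx = mask * g[..., None, None]
        gx = gx.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accum(gx)

    return Tensor._make(out, (x,), bwd)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation for NCHW tensors.

    ``running_mean``/``running_var`` are updated in place in training mode.
    """
    c = x.data.shape[1]
    shape = (1, c, 1, 1)
    if training:
        axes = (0, 2, 3)
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        # unbiased estimate for the running variance, biased for the batch
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mu = running_mean
        var = running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(shape)) * inv.reshape(shape)
    out = xhat * gamma.data.reshape(shape) + beta.data.reshape(shape)

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            beta._accum(g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        if not training:
            x._accum(g * (gamma.data * inv).reshape(shape))
            return
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        gxhat = g * gamma.data.reshape(shape)
        gsum = gxhat.sum(axis=(0, 2, 3)).reshape(shape)
        gdot = (gxhat * xhat).sum(axis=(0, 2, 3)).reshape(shape)
        gx = inv.reshape(shape) * (gxhat - gsum / m - xhat * gdot / m)
        x._accum(gx.astype(np.float32))

    return Tensor._make(out, (x, gamma, beta), bwd)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``labels`` are integer class indices."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = logits.data.shape[0]
    loss = -logp[np.arange(n), labels].mean()

    def bwd(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        logits._accum(g * p / n)

    return Tensor._make(np.float32(loss), (logits,), bwd)
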