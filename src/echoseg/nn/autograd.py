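"""Minimal reverse-mode autodiff on numpy arrays.

A :class:`Tensor` wraps a float32 numpy array and records, for each derived
tensor, its parents and a closure mapping the output gradient to parent
gradients; ``Tensor.backward()`` runs the closures in reverse topological
order.  Only the operations needed by the segmentation network are provided:
elementwise arithmetic, ReLU/sigmoid, concatenation, im2col convolution,
2×2 max-pooling, bilinear resizing and adaptive average pooling (both
expressed as fixed interpolation matrices applied per spatial axis), and
reductions.

Feature maps use **channels-last** layout ``(B, H, W, C)`` throughout: with
this layout the im2col buffer, the convolution output and the loss
reshapes are all contiguous, so every heavy operation is a single GEMM with
no transpose copies, which is what keeps CPU training viable.  Convolution
weights keep the conventional ``(Cout, Cin, KH, KW)`` shape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "relu",
    "sigmoid",
    "concat",
    "conv2d",
    "maxpool2x2",
    "bilinear_resize",
    "adaptive_avg_pool",
    "mean_all",
    "add_n",
    "pool_output_size",
]

_DTYPE = np.float32


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.ascontiguousarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph traversal ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=_DTYPE)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if pgrad is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad.astype(_DTYPE, copy=True)
                else:
                    parent.grad += pgrad

    def zero_grad(self) -> None:
        self.grad = None

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), Tensor(-1.0)))

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("tensor division only supports python scalars")
        return mul(self, Tensor(1.0 / scalar))

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=_DTYPE))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def add(a: Tensor, b: Tensor) -> Tensor:
    def bwd(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return Tensor(a.data + b.data, parents=(a, b), backward=bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bwd(g):
        return (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        )

    return Tensor(a.data * b.data, parents=(a, b), backward=bwd)


def add_n(tensors: list[Tensor]) -> Tensor:
    out = tensors[0]
    for t in tensors[1:]:
        out = add(out, t)
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, parents=(x,), backward=lambda g: (g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    # clip keeps exp finite in float32; saturates harmlessly
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0)))
    return Tensor(y, parents=(x,), backward=lambda g: (g * y * (1.0 - y),))


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(data, parents=tuple(tensors), backward=bwd)


def mean_all(x: Tensor) -> Tensor:
    n = x.data.size

    def bwd(g):
        return (np.full_like(x.data, np.asarray(g).item() / n),)

    return Tensor(np.array(x.data.mean()), parents=(x,), backward=bwd)


# ---------------------------------------------------------------------------
# convolution (channels-last)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation on ``(B, H, W, C)`` input.

    ``w`` is ``(Cout, Cin, KH, KW)``; its GEMM flattening order (Cin, KH, KW)
    matches the sliding-window column order, and a 1×1 kernel with no padding
    degenerates to a plain channel GEMM with zero-copy columns.
    """
    B, H, W, C = x.data.shape
    Cout, Cin, KH, KW = w.data.shape
    if Cin != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight expects {Cin}")
    OH = (H + 2 * padding - KH) // stride + 1
    OW = (W + 2 * padding - KW) // stride + 1
    if padding:
        xp = np.pad(x.data, ((0, 0), (padding, padding), (padding, padding), (0, 0)))
    else:
        xp = x.data
    if KH == KW == 1 and stride == 1:
        cols = xp.reshape(B, H * W, C)  # free view
    else:
        win = np.lib.stride_tricks.sliding_window_view(xp, (KH, KW), axis=(1, 2))
        win = win[:, ::stride, ::stride]  # (B, OH, OW, C, KH, KW)
        cols = win.reshape(B, OH * OW, C * KH * KW)  # one packed copy
    wmat = w.data.reshape(Cout, -1)
    out = cols @ wmat.T  # (B, OHW, Cout)
    if b is not None:
        out += b.data
    out = out.reshape(B, OH, OW, Cout)

    def bwd(g):
        gm = g.reshape(B * OH * OW, Cout)
        db = gm.sum(axis=0) if b is not None else None
        dw = (gm.T @ cols.reshape(B * OH * OW, -1)).reshape(w.data.shape)
        if KH == KW == 1 and stride == 1:
            dx = (gm @ wmat).reshape(B, H, W, C)
        else:
            # per-offset GEMMs: avoids materializing the KH·KW-times-larger
            # column-gradient array
            dxp = np.zeros_like(xp)
            for i in range(KH):
                for j in range(KW):
                    contrib = (gm @ w.data[:, :, i, j]).reshape(B, OH, OW, C)
                    dxp[
                        :, i : i + stride * OH : stride, j : j + stride * OW : stride, :
                    ] += contrib
            dx = dxp[:, padding : padding + H, padding : padding + W, :] if padding else dxp
        if b is not None:
            return dx, dw, db
        return dx, dw

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents=parents, backward=bwd)


def maxpool2x2(x: Tensor) -> Tensor:
    B, H, W, C = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2x2 requires even spatial dims")
    H2, W2 = H // 2, W // 2
    win = (
        x.data.reshape(B, H2, 2, W2, 2, C)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(B, H2, W2, 4, C)
    )
    idx = win.argmax(axis=3)  # ties → first window position: deterministic
    out = np.take_along_axis(win, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def bwd(g):
        gw = np.zeros((B, H2, W2, 4, C), dtype=_DTYPE)
        np.put_along_axis(gw, idx[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        dx = (
            gw.reshape(B, H2, W2, 2, 2, C)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(B, H, W, C)
        )
        return (dx,)

    return Tensor(out, parents=(x,), backward=bwd)


# ---------------------------------------------------------------------------
# resampling as fixed linear maps along each spatial axis


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Half-pixel-center linear interpolation matrix (n_out × n_in)."""
    m = np.zeros((n_out, n_in), dtype=_DTYPE)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = (src - i0).astype(_DTYPE)
    for r in range(n_out):
        m[r, i0[r]] += 1.0 - frac[r]
        m[r, i1[r]] += frac[r]
    return m


def _avgpool_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Adaptive average-pool matrix; region i covers [⌊i·n/b⌋, ⌈(i+1)·n/b⌉)."""
    m = np.zeros((n_out, n_in), dtype=_DTYPE)
    for i in range(n_out):
        lo = (i * n_in) // n_out
        hi = -(-((i + 1) * n_in) // n_out)  # ceil
        m[i, lo:hi] = 1.0 / (hi - lo)
    return m


def _apply_axes(x: np.ndarray, my: np.ndarray, mx: np.ndarray) -> np.ndarray:
    """y[b,o,p,c] = Σ_{h,w} my[o,h] x[b,h,w,c] mx[p,w], as two batched GEMMs."""
    B, H, W, C = x.shape
    oh, ow = my.shape[0], mx.shape[0]
    t = np.matmul(my, x.reshape(B, H, W * C))  # (B, OH, W*C)
    t = np.matmul(mx, t.reshape(B * oh, W, C))  # (B*OH, OW, C)
    return t.reshape(B, oh, ow, C)


def _linear_resample(x: Tensor, my: np.ndarray, mx: np.ndarray) -> Tensor:
    out = _apply_axes(x.data, my, mx)

    def bwd(g):
        return (_apply_axes(g, my.T, mx.T),)

    return Tensor(out, parents=(x,), backward=bwd)


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize (half-pixel centers) to ``out_hw``."""
    _, H, W, _ = x.data.shape
    oh, ow = out_hw
    if (oh, ow) == (H, W):
        return x
    return _linear_resample(x, _bilinear_matrix(oh, H), _bilinear_matrix(ow, W))


def adaptive_avg_pool(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Average-pool to an ``out_hw`` grid of near-equal contiguous regions."""
    _, H, W, _ = x.data.shape
    oh, ow = out_hw
    if oh > H or ow > W:
        raise ValueError(f"pool grid {out_hw} larger than input {(H, W)}")
    return _linear_resample(x, _avgpool_matrix(oh, H), _avgpool_matrix(ow, W))


def pool_output_size(i: int, k: int, s: int) -> int:
    """Valid-pooling output size (I − K)/S + 1."""
    if (i - k) % s:
        raise ValueError("kernel/stride do not tile the input")
    return (i - k) // s + 1
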