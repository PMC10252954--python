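"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for small encoder–decoder convolutional networks on
CPU: N-dimensional convolution (2-D and 3-D), batch normalization, leaky
ReLU, sigmoid, nearest-neighbour upsampling, concatenation and the loss
primitives used in training.  Deliberately eager and single-threaded:
reproducibility and transparency over speed.
"""
from __future__ import annotations

import itertools
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

EPS = 1e-7


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Tuple["Tensor", ...] = (), backward=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float32)
        self.data = data
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)
        self._backward = backward
        self._parents = parents

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, self.data.dtype).copy()
        else:
            self.grad += np.asarray(g, self.data.dtype)

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor):
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

    # tiny arithmetic surface (losses are combined with + and scalar *)
    def __add__(self, other):
        if not isinstance(other, Tensor):
            other = Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.accumulate(g)
            if other.requires_grad:
                other.accumulate(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, scalar: float):
        s = float(scalar)
        out = Tensor(self.data * s, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.accumulate(g * s)

        out._backward = bw
        return out

    __rmul__ = __mul__


# ---------------------------------------------------------------------------
# layers / activations
# ---------------------------------------------------------------------------

def _conv_out_shape(spatial, k, stride):
    return tuple((s + 2 * (k // 2) - k) // stride + 1 for s in spatial)


def conv_nd(x: Tensor, w: Tensor, b: Optional[Tensor], stride: int = 1) -> Tensor:
    """N-d convolution ('same' zero padding of k//2, square kernel)."""
    rank = x.data.ndim - 2
    k = w.data.shape[2]
    pad = k // 2
    spatial = x.data.shape[2:]
    out_sp = _conv_out_shape(spatial, k, stride)
    pads = [(0, 0), (0, 0)] + [(pad, pad)] * rank
    xp = np.pad(x.data, pads)
    n, o = x.data.shape[0], w.data.shape[0]
    out = np.zeros((n, o, *out_sp), np.float32)
    offsets = list(itertools.product(*[range(k)] * rank))
    slices = {
        off: tuple(
            slice(off[d], off[d] + stride * (out_sp[d] - 1) + 1, stride)
            for d in range(rank))
        for off in offsets
    }
    for off in offsets:
        xs = xp[(slice(None), slice(None)) + slices[off]]
        out += np.einsum("nc...,oc->no...", xs, w.data[(...,) + off])
    if b is not None:
        out += b.data.reshape((1, -1) + (1,) * rank)
    parents = (x, w) + ((b,) if b is not None else ())
    t = Tensor(out, parents=parents)

    def bw(g):
        if w.requires_grad:
            dw = np.zeros_like(w.data)
            red = [0] + list(range(2, g.ndim))
            for off in offsets:
                xs = xp[(slice(None), slice(None)) + slices[off]]
                dw[(...,) + off] = np.tensordot(g, xs, axes=(red, red))
            w.accumulate(dw)
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0,) + tuple(range(2, g.ndim))))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for off in offsets:
                dxp[(slice(None), slice(None)) + slices[off]] += np.einsum(
                    "no...,oc->nc...", g, w.data[(...,) + off])
            sl = (slice(None), slice(None)) + tuple(
                slice(pad, pad + s) for s in spatial)
            x.accumulate(dxp[sl])

    t._backward = bw
    return t


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    out = Tensor(np.where(x.data > 0, x.data, slope * x.data), parents=(x,))

    def bw(g):
        if x.requires_grad:
            x.accumulate(np.where(x.data > 0, 1.0, slope) * g)

    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x.accumulate(g * s * (1.0 - s))

    out._backward = bw
    return out


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean,
               running_var, training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    axes = (0,) + tuple(range(2, x.data.ndim))
    shape = (1, -1) + (1,) * (x.data.ndim - 2)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(shape)) * inv.reshape(shape)
    out = Tensor(gamma.data.reshape(shape) * xhat + beta.data.reshape(shape),
                 parents=(x, gamma, beta))

    def bw(g):
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=axes))
        if x.requires_grad:
            if training:
                m = float(np.prod([x.data.shape[a] for a in axes]))
                gm = g.mean(axis=axes).reshape(shape)
                gxm = (g * xhat).mean(axis=axes).reshape(shape)
                dx = (gamma.data.reshape(shape) * inv.reshape(shape)
                      * (g - gm - xhat * gxm))
            else:
                dx = gamma.data.reshape(shape) * inv.reshape(shape) * g
            x.accumulate(dx)

    out._backward = bw
    return out


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    rank = x.data.ndim - 2
    out_data = x.data
    for ax in range(2, 2 + rank):
        out_data = np.repeat(out_data, factor, axis=ax)
    out = Tensor(out_data, parents=(x,))

    def bw(g):
        if x.requires_grad:
            for ax in range(2, 2 + rank):
                s = list(g.shape)
                s[ax] = s[ax] // factor
                s.insert(ax + 1, factor)
                g = g.reshape(s).sum(axis=ax + 1)
            x.accumulate(g)

    out._backward = bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def bw(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + s)
                t.accumulate(g[tuple(sl)])
            start += s

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def l1_loss(pred: Tensor, target: np.ndarray,
            mask: Optional[np.ndarray] = None) -> Tensor:
    """Mean absolute difference, optionally restricted to a (broadcastable)
    mask; the mean is over masked elements."""
    diff = pred.data - target
    if mask is None:
        n = diff.size
        val = np.abs(diff).sum() / n
        grad_w = np.ones_like(diff) / n
    else:
        m = np.broadcast_to(mask, diff.shape).astype(np.float32)
        n = max(float(m.sum()), 1.0)
        val = float((np.abs(diff) * m).sum() / n)
        grad_w = m / n
    out = Tensor(val, parents=(pred,))

    def bw(g):
        if pred.requires_grad:
            pred.accumulate(g * np.sign(diff) * grad_w)

    out._backward = bw
    return out


def bce_discriminator(d_real: Tensor, d_fake: Tensor) -> Tensor:
    """-(mean log D(real) + mean log(1 - D(fake))); scores clamped to
    (EPS, 1-EPS)."""
    r = np.clip(d_real.data, EPS, 1.0 - EPS)
    f = np.clip(d_fake.data, EPS, 1.0 - EPS)
    val = -(np.mean(np.log(r)) + np.mean(np.log(1.0 - f)))
    out = Tensor(val, parents=(d_real, d_fake))

    def bw(g):
        if d_real.requires_grad:
            d_real.accumulate(-g / (r * r.size))
        if d_fake.requires_grad:
            d_fake.accumulate(g / ((1.0 - f) * f.size))

    out._backward = bw
    return out


def bce_generator(d_fake: Tensor) -> Tensor:
    """Non-saturating generator objective: -mean log D(fake)."""
    f = np.clip(d_fake.data, EPS, 1.0 - EPS)
    out = Tensor(-np.mean(np.log(f)), parents=(d_fake,))

    def bw(g):
        if d_fake.requires_grad:
            d_fake.accumulate(-g / (f * f.size))

    out._backward = bw
    return out


def _laplacian_stencil(arr: np.ndarray) -> np.ndarray:
    """Voxel-unit 7-point Laplacian of (N, C, D, H, W) on the interior,
    zero elsewhere (shape preserved)."""
    out = np.zeros_like(arr)
    core = arr[..., 1:-1, 1:-1, 1:-1]
    lap = -6.0 * core
    lap = lap + arr[..., 2:, 1:-1, 1:-1] + arr[..., :-2, 1:-1, 1:-1]
    lap = lap + arr[..., 1:-1, 2:, 1:-1] + arr[..., 1:-1, :-2, 1:-1]
    lap = lap + arr[..., 1:-1, 1:-1, 2:] + arr[..., 1:-1, 1:-1, :-2]
    out[..., 1:-1, 1:-1, 1:-1] = lap
    return out


def _laplacian_adjoint(lap_interior: np.ndarray) -> np.ndarray:
    """Adjoint of ``_laplacian_stencil`` (symmetric stencil, zero-padded)."""
    out = np.zeros_like(lap_interior)
    L = np.zeros_like(lap_interior)
    L[..., 1:-1, 1:-1, 1:-1] = lap_interior[..., 1:-1, 1:-1, 1:-1]
    out -= 6.0 * L
    out[..., 1:, :, :] += L[..., :-1, :, :]
    out[..., :-1, :, :] += L[..., 1:, :, :]
    out[..., :, 1:, :] += L[..., :, :-1, :]
    out[..., :, :-1, :] += L[..., :, 1:, :]
    out[..., :, :, 1:] += L[..., :, :, :-1]
    out[..., :, :, :-1] += L[..., :, :, 1:]
    return out


def curvature_penalty(dvf: Tensor) -> Tensor:
    """Mean (over batch and interior voxels) squared Laplacian, summed over
    displacement components; voxel-unit discretization on patches."""
    arr = dvf.data
    n_interior = int(np.prod([s - 2 for s in arr.shape[2:]]))
    denom = arr.shape[0] * max(n_interior, 1)
    lap = _laplacian_stencil(arr)
    # sum over channels of mean over batch+interior
    val = float((lap ** 2).sum() / denom)
    out = Tensor(val, parents=(dvf,))

    def bw(g):
        if dvf.requires_grad:
            dvf.accumulate(g * 2.0 * _laplacian_adjoint(lap) / denom)

    out._backward = bw
    return out


def warp_l1_loss(dvf: Tensor, moving: np.ndarray, target: np.ndarray,
                 mask: np.ndarray, scale_vox: np.ndarray) -> Tensor:
    """L1 intensity loss between the target and the moving image warped by
    the predicted displacement (pull-back, trilinear).

    ``dvf`` is (N, 3, D, H, W) in normalized units; ``scale_vox[c]``
    converts component c to voxels.  The gradient with respect to the
    displacement uses the spatial gradient of the moving image sampled at
    the warped positions (the standard first-order approximation).
    """
    from scipy import ndimage  # local import: keeps numpy-only core clean

    n = dvf.data.shape[0]
    spatial = dvf.data.shape[2:]
    idx = np.indices(spatial).astype(np.float64)
    msum = max(float(mask.sum()), 1.0)
    warped = np.empty_like(target)
    grads = np.empty((n, 3, *spatial), np.float64)
    for i in range(n):
        coords = [idx[c] + dvf.data[i, c] * scale_vox[c] for c in range(3)]
        mov = moving[i, 0].astype(np.float64)
        warped[i, 0] = ndimage.map_coordinates(
            mov, coords, order=1, mode="nearest")
        g = np.gradient(mov)
        for c in range(3):
            grads[i, c] = ndimage.map_coordinates(
                g[c], coords, order=1, mode="nearest")
    diff = warped - target
    val = float((np.abs(diff) * mask).sum() / msum)
    out = Tensor(val, parents=(dvf,))

    def bw(gout):
        if dvf.requires_grad:
            sign = np.sign(diff) * mask / msum
            d = np.empty_like(dvf.data)
            for c in range(3):
                d[:, c] = (sign[:, 0] * grads[:, c] * scale_vox[c]).astype(
                    np.float32)
            dvf.accumulate(gout * d)

    out._backward = bw
    return out
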