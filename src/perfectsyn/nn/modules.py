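"""Network building blocks: convolutional encoder–decoder generators with
skip connections and a conditional patch discriminator."""
from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np

from .autograd import (
    Tensor,
    batch_norm,
    concat,
    conv_nd,
    leaky_relu,
    sigmoid,
    upsample_nearest,
)


class Module:
    def __init__(self):
        self.training = True
        self._modules: List["Module"] = []
        self._params: Dict[str, Tensor] = {}

    def register(self, module: "Module") -> "Module":
        self._modules.append(module)
        return module

    def parameters(self) -> List[Tensor]:
        out = list(self._params.values())
        for m in self._modules:
            out.extend(m.parameters())
        return out

    def named_state(self, prefix: str = "") -> Dict[str, np.ndarray]:
        out = {prefix + k: v.data for k, v in self._params.items()}
        for i, m in enumerate(self._modules):
            out.update(m.named_state(f"{prefix}{i}."))
        return out

    def load_state(self, state: Dict[str, np.ndarray], prefix: str = "") -> None:
        for k, v in self._params.items():
            v.data = np.asarray(state[prefix + k], np.float32).copy()
        for i, m in enumerate(self._modules):
            m.load_state(state, f"{prefix}{i}.")

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules:
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


class Conv(Module):
    """Convolution with He-style initialization for leaky-ReLU networks."""

    def __init__(self, rank: int, c_in: int, c_out: int, k: int = 3,
                 stride: int = 1, rng: Optional[np.random.Generator] = None,
                 bias: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k ** rank
        std = np.sqrt(2.0 / fan_in)
        self.stride = stride
        self._params["w"] = Tensor(
            rng.normal(0.0, std, (c_out, c_in) + (k,) * rank)
            .astype(np.float32), requires_grad=True)
        self._params["b"] = Tensor(np.zeros(c_out, np.float32),
                                   requires_grad=True) if bias else None
        if self._params["b"] is None:
            del self._params["b"]
        self.has_bias = bias

    def __call__(self, x: Tensor) -> Tensor:
        return conv_nd(x, self._params["w"],
                       self._params.get("b"), stride=self.stride)


class BatchNorm(Module):
    def __init__(self, c: int):
        super().__init__()
        self._params["gamma"] = Tensor(np.ones(c, np.float32),
                                       requires_grad=True)
        self._params["beta"] = Tensor(np.zeros(c, np.float32),
                                      requires_grad=True)
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        return batch_norm(x, self._params["gamma"], self._params["beta"],
                          self.running_mean, self.running_var, self.training)

    def named_state(self, prefix: str = ""):
        out = super().named_state(prefix)
        out[prefix + "running_mean"] = self.running_mean
        out[prefix + "running_var"] = self.running_var
        return out

    def load_state(self, state, prefix: str = ""):
        super().load_state(state, prefix)
        self.running_mean = np.asarray(state[prefix + "running_mean"],
                                       np.float32).copy()
        self.running_var = np.asarray(state[prefix + "running_var"],
                                      np.float32).copy()


class ConvBlock(Module):
    """Conv -> BatchNorm -> LeakyReLU (batch norm on the conv output)."""

    def __init__(self, rank, c_in, c_out, stride, slope, rng, norm=True):
        super().__init__()
        self.conv = self.register(Conv(rank, c_in, c_out, 3, stride, rng))
        self.bn = self.register(BatchNorm(c_out)) if norm else None
        self.slope = slope

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv(x)
        if self.bn is not None:
            h = self.bn(h)
        return leaky_relu(h, self.slope)


class UNet(Module):
    """Encoder–decoder with skip connections emitting a displacement field.

    The final projection is linear: displacements are signed, unbounded
    reals, so no squashing activation is applied.
    """

    def __init__(self, rank: int, c_in: int, c_out: int, base: int,
                 depth: int, slope: float,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.depth = depth
        widths = [min(base * 2 ** d, 8 * base) for d in range(depth + 1)]
        self.enc = []
        c = c_in
        for d in range(depth):
            blk = self.register(ConvBlock(rank, c, widths[d], 1, slope, rng))
            down = self.register(ConvBlock(rank, widths[d], widths[d + 1], 2,
                                           slope, rng))
            self.enc.append((blk, down))
            c = widths[d + 1]
        self.bottleneck = self.register(ConvBlock(rank, c, c, 1, slope, rng))
        self.dec = []
        for d in reversed(range(depth)):
            up = self.register(ConvBlock(rank, c, widths[d], 1, slope, rng))
            fuse = self.register(ConvBlock(rank, widths[d] * 2, widths[d], 1,
                                           slope, rng))
            self.dec.append((up, fuse))
            c = widths[d]
        self.head = self.register(Conv(rank, c, c_out, 1, 1, rng))

    def __call__(self, x: Tensor) -> Tensor:
        skips = []
        h = x
        for blk, down in self.enc:
            s = blk(h)
            skips.append(s)
            h = down(s)
        h = self.bottleneck(h)
        for (up, fuse), s in zip(self.dec, reversed(skips)):
            h = up(upsample_nearest(h, 2))
            h = fuse(concat([h, s], axis=1))
        return self.head(h)


class PatchDiscriminator(Module):
    """Conditional patch critic: scores (input CT, displacement field)
    pairs through strided convolutions; sigmoid output in (0, 1)."""

    def __init__(self, rank: int, c_in: int, base: int, slope: float,
                 n_layers: int = 3,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.blocks = []
        c = c_in
        w = base
        for i in range(n_layers):
            blk = self.register(
                ConvBlock(rank, c, w, 2, slope, rng, norm=(i > 0)))
            self.blocks.append(blk)
            c, w = w, min(w * 2, 8 * base)
        self.head = self.register(Conv(rank, c, 1, 3, 1, rng))

    def __call__(self, ct: Tensor, dvf: Tensor) -> Tensor:
        h = concat([ct, dvf], axis=1)
        for blk in self.blocks:
            h = blk(h)
        return sigmoid(self.head(h))
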