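"""Composite convolutional blocks: C2f, C2f+LSKA, SPPF, and SPPF-CA.

SPPF-CA replaces the serial max-pooling cascade of classic SPPF with a
cascade of separable 5-tap depthwise stages (1×5 then 5×1), gates each
stage's features with coordinate attention computed from the preceding
stage, and concatenates the entry features with the three gated stage
outputs before the exit 1×1 convolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .attention import LSKA, CoordAtt
from .nn import Tensor
from .nn.tensor import maxpool2d_forward

__all__ = [
    "C2fConfig",
    "SPPFCAConfig",
    "ConvBNAct",
    "Bottleneck",
    "C2f",
    "C2fLSKA",
    "SPPF",
    "SPPFCA",
    "c2f_forward",
    "c2f_lska_forward",
    "sppf_forward",
    "sppf_ca_forward",
]


@dataclass(frozen=True)
class C2fConfig:
    """n bottlenecks on one half of a split ``c``-channel feature map."""

    c_in: int
    c: int
    n: int = 1
    shortcut: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.c % 2:
            raise ValueError(f"C2f channel count must be even, got {self.c}")
        if self.n < 1:
            raise ValueError("need at least one bottleneck")


@dataclass(frozen=True)
class SPPFCAConfig:
    c_in: int
    c_out: int
    stages: int = 3
    ca_r: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.stages < 1:
            raise ValueError("need at least one depthwise stage")


class ConvBNAct(nn.Module):
    """Conv → batch-norm → SiLU, the standard stabilized convolution unit."""

    def __init__(self, c_in: int, c_out: int, k, *, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, k, stride=stride, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        return nn.silu(self.bn(self.conv(x)))


class Bottleneck(nn.Module):
    """Two 3×3 convolutions with an optional residual shortcut."""

    def __init__(self, c: int, shortcut: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cv1 = ConvBNAct(c, c, 3, rng=rng)
        self.cv2 = ConvBNAct(c, c, 3, rng=rng)
        self.shortcut = shortcut

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y


class C2f(nn.Module):
    """Split/bottleneck/concat block.

    The entry 1×1 produces ``c`` channels split into two 0.5c halves; one half
    passes through ``n`` bottlenecks with shortcut accumulation, the other
    bypasses; the concatenation goes through the exit 1×1.
    """

    def __init__(self, c_in: int, c: int, n: int = 1, shortcut: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if c % 2:
            raise ValueError(f"C2f channel count must be even, got {c}")
        rng = rng or np.random.default_rng(0)
        self.c = c
        self.cv1 = ConvBNAct(c_in, c, 1, rng=rng)
        self.blocks = [Bottleneck(c // 2, shortcut, rng=rng) for _ in range(n)]
        self.cv2 = ConvBNAct(c, c, 1, rng=rng)

    @classmethod
    def from_config(cls, cfg: C2fConfig) -> "C2f":
        return cls(cfg.c_in, cfg.c, cfg.n, cfg.shortcut,
                   rng=np.random.default_rng(cfg.seed))

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        half = self.c // 2
        a = y[:, :half, :, :]
        b = y[:, half:, :, :]
        for blk in self.blocks:
            b = blk(b)
        return self.cv2(nn.concat([a, b], axis=1))


class C2fLSKA(nn.Module):
    """C2f followed by an LSKA attention block (the attention-augmented backbone unit)."""

    def __init__(self, c_in: int, c: int, n: int = 1, shortcut: bool = True,
                 k: int = 11, d: int = 3, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c2f = C2f(c_in, c, n, shortcut, rng=rng)
        self.lska = LSKA(c, k, d, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.lska(self.c2f(x))


class SPPF(nn.Module):
    """Classic spatial pyramid pooling (fast): serial 5×5 max-pool cascade."""

    def __init__(self, c_in: int, c_out: int, k: int = 5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        ch = max(1, c_in // 2)
        self.k = k
        self.cv1 = ConvBNAct(c_in, ch, 1, rng=rng)
        self.cv2 = ConvBNAct(4 * ch, c_out, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y0 = self.cv1(x)
        y1 = nn.maxpool2d(y0, self.k)
        y2 = nn.maxpool2d(y1, self.k)
        y3 = nn.maxpool2d(y2, self.k)
        return self.cv2(nn.concat([y0, y1, y2, y3], axis=1))


class SPPFCA(nn.Module):
    """SPPF with max pooling replaced by separable depthwise stages + CA gates.

    Stage i computes f_i = DW_{5×1}(DW_{1×5}(f_{i−1})) and its gated output
    out_i = f_i ⊗ g_h(f_{i−1}) ⊗ g_w(f_{i−1}), where (g_h, g_w) are the
    coordinate-attention gates of the preceding stage's features and f_0 is
    the entry 1×1 output.  The exit 1×1 consumes concat(f_0, out_1, …,
    out_s).  CA weights are not shared across stages.
    """

    def __init__(self, c_in: int, c_out: int, stages: int = 3, ca_r: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        ch = max(1, c_in // 2)
        self.stages = stages
        self.cv1 = ConvBNAct(c_in, ch, 1, rng=rng)
        self.dw_h = [nn.Conv2d(ch, ch, (1, 5), groups=ch, bias=False, rng=rng)
                     for _ in range(stages)]
        self.dw_v = [nn.Conv2d(ch, ch, (5, 1), groups=ch, bias=False, rng=rng)
                     for _ in range(stages)]
        self.ca = [CoordAtt(ch, min(ca_r, ch), rng=rng) for _ in range(stages)]
        self.cv2 = ConvBNAct((stages + 1) * ch, c_out, 1, rng=rng)

    @classmethod
    def from_config(cls, cfg: SPPFCAConfig) -> "SPPFCA":
        return cls(cfg.c_in, cfg.c_out, cfg.stages, cfg.ca_r,
                   rng=np.random.default_rng(cfg.seed))

    def forward(self, x: Tensor) -> Tensor:
        f = self.cv1(x)
        feats = [f]
        prev = f
        for i in range(self.stages):
            fi = self.dw_v[i](self.dw_h[i](prev))
            gh, gw = self.ca[i].gates(prev)
            feats.append(fi * gh * gw)
            prev = fi
        return self.cv2(nn.concat(feats, axis=1))


# -- functional wrappers on (C, H, W) arrays -----------------------------

def _apply(module: nn.Module, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    module.eval()
    return module(Tensor(x[None])).data[0]


def c2f_forward(x: np.ndarray, cfg: C2fConfig | C2f) -> np.ndarray:
    block = cfg if isinstance(cfg, C2f) else C2f.from_config(cfg)
    return _apply(block, x)


def c2f_lska_forward(x: np.ndarray, block: C2fLSKA) -> np.ndarray:
    return _apply(block, x)


def sppf_forward(x: np.ndarray, block: SPPF) -> np.ndarray:
    return _apply(block, x)


def sppf_ca_forward(x: np.ndarray, cfg: SPPFCAConfig | SPPFCA) -> np.ndarray:
    block = cfg if isinstance(cfg, SPPFCA) else SPPFCA.from_config(cfg)
    return _apply(block, x)
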