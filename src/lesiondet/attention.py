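"""Attention operators: large separable kernel attention and coordinate attention.

Large separable kernel attention (LSKA) approximates a large-kernel depthwise
attention (LKA) by factoring each 2-D depthwise kernel into a horizontal and a
vertical 1-D kernel.  The cascade is:

    1×(2d−1) DW  →  (2d−1)×1 DW  →  1×⌊k/d⌋ DW (dilation d)
                 →  ⌊k/d⌋×1 DW (dilation d)  →  1×1 conv  =  attention map A

and the output is the elementwise product A ⊗ x.  When every 2-D kernel of
LKA is exactly the outer product of the corresponding 1-D pair (rank-1), the
two operators coincide; :func:`lka_forward` is kept as the brute-force oracle
for that equivalence and is not used by the detector itself.

Coordinate attention (CA) pools each channel along width and along height
separately, mixes the two pooled profiles through a shared 1×1 reduction
(ratio ``r``) with normalization and a nonlinearity, and emits per-row and
per-column sigmoid gates:  y_c(i,j) = x_c(i,j) · g_h(i) · g_w(j).

Two surfaces are provided: stateless functional ops on (C, H, W) arrays with
explicit weight containers (used for oracle tests and inspection), and
:class:`LSKA` / :class:`CoordAtt` modules with learnable parameters used by
the detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .nn.tensor import conv2d_forward

__all__ = [
    "LSKAConfig",
    "CAConfig",
    "lska_forward",
    "lska_attention_map",
    "lka_forward",
    "ca_forward",
    "ca_gates",
    "LSKA",
    "CoordAtt",
]


def _lengths(k: int, d: int) -> tuple[int, int]:
    """1-D kernel lengths for the local and dilated separable pairs."""
    if k < 1 or d < 1 or k < d:
        raise ValueError(f"need k >= d >= 1, got k={k}, d={d}")
    local = 2 * d - 1
    dil = k // d
    if dil % 2 == 0:
        raise ValueError(
            f"decomposed dilated kernel length k//d = {dil} is even; "
            "shape-preserving padding requires odd lengths")
    return local, dil


@dataclass
class LSKAConfig:
    """Weights for one LSKA operator on ``c`` channels.

    ``h_local``/``v_local`` are (c, 2d−1) 1-D depthwise taps, ``h_dil``/
    ``v_dil`` are (c, ⌊k/d⌋) taps applied with dilation ``d``, and ``mix`` is
    the (c, c) 1×1 channel-mixing matrix producing the attention map.
    """

    k: int
    d: int
    h_local: np.ndarray
    v_local: np.ndarray
    h_dil: np.ndarray
    v_dil: np.ndarray
    mix: np.ndarray
    mix_bias: np.ndarray | None = None

    def __post_init__(self):
        local, dil = _lengths(self.k, self.d)
        c = self.mix.shape[0]
        for name, arr, ln in (("h_local", self.h_local, local),
                              ("v_local", self.v_local, local),
                              ("h_dil", self.h_dil, dil),
                              ("v_dil", self.v_dil, dil)):
            if arr.shape != (c, ln):
                raise ValueError(f"{name} must have shape {(c, ln)}, got {arr.shape}")
        if self.mix.shape != (c, c):
            raise ValueError("mix must be square (c, c)")

    @property
    def channels(self) -> int:
        return self.mix.shape[0]

    @classmethod
    def random(cls, c: int, k: int = 11, d: int = 3,
               rng: np.random.Generator | None = None) -> "LSKAConfig":
        rng = rng or np.random.default_rng(0)
        local, dil = _lengths(k, d)
        s = rng.standard_normal
        return cls(k, d, s((c, local)), s((c, local)), s((c, dil)), s((c, dil)),
                   s((c, c)))

    @classmethod
    def identity(cls, c: int, k: int = 11, d: int = 3) -> "LSKAConfig":
        """Centered-delta taps and unit mixing: the attention map equals x."""
        local, dil = _lengths(k, d)

        def delta(ln):
            t = np.zeros((c, ln))
            t[:, ln // 2] = 1.0
            return t

        return cls(k, d, delta(local), delta(local), delta(dil), delta(dil),
                   np.eye(c))


def _dw_1d(x: np.ndarray, taps: np.ndarray, axis: str, dilation: int = 1) -> np.ndarray:
    """Depthwise 1-D convolution of (C, H, W) along 'h' (width) or 'v' (height)."""
    c = x.shape[0]
    if axis == "h":
        w = taps[:, None, None, :]
    else:
        w = taps[:, None, :, None]
    return conv2d_forward(x[None], w, dilation=dilation, groups=c)[0]


def lska_attention_map(x: np.ndarray, cfg: LSKAConfig) -> np.ndarray:
    """The separable-cascade attention map A for input x of shape (C, H, W)."""
    x = np.asarray(x, dtype=np.float64)
    z = _dw_1d(x, cfg.h_local, "h")
    z = _dw_1d(z, cfg.v_local, "v")
    z = _dw_1d(z, cfg.h_dil, "h", dilation=cfg.d)
    z = _dw_1d(z, cfg.v_dil, "v", dilation=cfg.d)
    a = np.einsum("oc,chw->ohw", cfg.mix, z)
    if cfg.mix_bias is not None:
        a = a + cfg.mix_bias[:, None, None]
    return a


def lska_forward(x: np.ndarray, cfg: LSKAConfig) -> np.ndarray:
    """LSKA output A ⊗ x; shape-preserving on (C, H, W)."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("input feature map contains non-finite values")
    return lska_attention_map(x, cfg) * x


def lka_forward(x: np.ndarray, w_local: np.ndarray, w_dil: np.ndarray,
                mix: np.ndarray, d: int) -> np.ndarray:
    """Brute-force large-kernel attention with full 2-D depthwise kernels.

    ``w_local`` is (C, 2d−1, 2d−1) applied densely, ``w_dil`` is
    (C, m, m) applied with dilation ``d``, ``mix`` is the (C, C) 1×1.
    Serves only as the independent oracle for :func:`lska_forward`.
    """
    x = np.asarray(x, dtype=np.float64)
    c = x.shape[0]
    z = conv2d_forward(x[None], w_local[:, None], groups=c)[0]
    z = conv2d_forward(z[None], w_dil[:, None], dilation=d, groups=c)[0]
    a = np.einsum("oc,chw->ohw", mix, z)
    return a * x


@dataclass
class CAConfig:
    """Weights for one coordinate-attention operator on ``c`` channels.

    ``w1`` (c//r, c) is the shared reduction applied to the concatenated
    height/width pooled profiles; ``wh``/``ww`` (c, c//r) map back to
    per-direction gates.  ``delta`` selects the mid nonlinearity.
    """

    r: int
    w1: np.ndarray
    wh: np.ndarray
    ww: np.ndarray
    b1: np.ndarray | None = None
    bh: np.ndarray | None = None
    bw: np.ndarray | None = None
    delta: str = "hardswish"
    bn_gamma: np.ndarray | None = None
    bn_beta: np.ndarray | None = None
    bn_eps: float = 1e-5

    def __post_init__(self):
        cr, c = self.w1.shape
        if self.r < 1 or c // self.r < 1:
            raise ValueError(f"reduction ratio r={self.r} exceeds channel count {c}")
        if cr != max(1, c // self.r):
            raise ValueError("w1 rows must equal max(1, c // r)")
        if self.wh.shape != (c, cr) or self.ww.shape != (c, cr):
            raise ValueError("wh/ww must have shape (c, c//r)")
        if self.delta not in ("hardswish", "sigmoid"):
            raise ValueError("delta must be 'hardswish' or 'sigmoid'")

    @property
    def channels(self) -> int:
        return self.w1.shape[1]

    @classmethod
    def random(cls, c: int, r: int = 4, rng: np.random.Generator | None = None,
               delta: str = "hardswish") -> "CAConfig":
        rng = rng or np.random.default_rng(0)
        cr = max(1, c // r)
        s = rng.standard_normal
        return cls(r, s((cr, c)), s((c, cr)), s((c, cr)), delta=delta)

    @classmethod
    def unit_gates(cls, c: int, r: int = 4) -> "CAConfig":
        """Zero gate weights with saturated positive bias: gates ≈ 1, y ≈ x."""
        cr = max(1, c // r)
        return cls(r, np.zeros((cr, c)), np.zeros((c, cr)), np.zeros((c, cr)),
                   bh=np.full(c, 30.0), bw=np.full(c, 30.0))


def _np_sigmoid(v):
    out = np.empty_like(v)
    pos = v >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
    e = np.exp(v[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _np_hardswish(v):
    return v * np.clip(v + 3.0, 0.0, 6.0) / 6.0


def ca_gates(x: np.ndarray, cfg: CAConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-row and per-column gates (g_h of shape (C, H), g_w of shape (C, W))."""
    x = np.asarray(x, dtype=np.float64)
    c, h, w = x.shape
    zh = x.mean(axis=2)                      # (C, H): average over width
    zw = x.mean(axis=1)                      # (C, W): average over height
    f = cfg.w1 @ np.concatenate([zh, zw], axis=1)   # (C/r, H+W)
    if cfg.b1 is not None:
        f = f + cfg.b1[:, None]
    # per-channel normalization over the concatenated spatial axis
    mu = f.mean(axis=1, keepdims=True)
    var = f.var(axis=1, keepdims=True)
    f = (f - mu) / np.sqrt(var + cfg.bn_eps)
    if cfg.bn_gamma is not None:
        f = f * cfg.bn_gamma[:, None]
    if cfg.bn_beta is not None:
        f = f + cfg.bn_beta[:, None]
    f = _np_hardswish(f) if cfg.delta == "hardswish" else _np_sigmoid(f)
    fh, fw = f[:, :h], f[:, h:]
    gh = cfg.wh @ fh
    gw = cfg.ww @ fw
    if cfg.bh is not None:
        gh = gh + cfg.bh[:, None]
    if cfg.bw is not None:
        gw = gw + cfg.bw[:, None]
    return _np_sigmoid(gh), _np_sigmoid(gw)


def ca_forward(x: np.ndarray, cfg: CAConfig) -> np.ndarray:
    """Coordinate-attention output y_c(i,j) = x_c(i,j)·g_h(i)·g_w(j)."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("input feature map contains non-finite values")
    gh, gw = ca_gates(x, cfg)
    return x * gh[:, :, None] * gw[:, None, :]


# -- trainable modules ---------------------------------------------------

class LSKA(nn.Module):
    """Learnable LSKA block operating on (N, C, H, W) tensors."""

    def __init__(self, c: int, k: int = 11, d: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        local, dil = _lengths(k, d)
        rng = rng or np.random.default_rng(0)
        self.k, self.d = k, d
        self.dw_h = nn.Conv2d(c, c, (1, local), groups=c, bias=False, rng=rng)
        self.dw_v = nn.Conv2d(c, c, (local, 1), groups=c, bias=False, rng=rng)
        self.dwd_h = nn.Conv2d(c, c, (1, dil), dilation=d, groups=c, bias=False, rng=rng)
        self.dwd_v = nn.Conv2d(c, c, (dil, 1), dilation=d, groups=c, bias=False, rng=rng)
        self.pw = nn.Conv2d(c, c, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        a = self.pw(self.dwd_v(self.dwd_h(self.dw_v(self.dw_h(x)))))
        return a * x


class CoordAtt(nn.Module):
    """Learnable coordinate-attention block operating on (N, C, H, W) tensors."""

    def __init__(self, c: int, r: int = 4, delta: str = "hardswish",
                 rng: np.random.Generator | None = None):
        super().__init__()
        if c // r < 1:
            raise ValueError(f"reduction ratio r={r} exceeds channel count {c}")
        rng = rng or np.random.default_rng(0)
        cr = max(1, c // r)
        self.delta = delta
        self.conv1 = nn.Conv2d(c, cr, 1, rng=rng)
        self.bn = nn.BatchNorm2d(cr)
        self.conv_h = nn.Conv2d(cr, c, 1, rng=rng)
        self.conv_w = nn.Conv2d(cr, c, 1, rng=rng)

    def gates(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Per-row and per-column multiplicative gates derived from ``x``."""
        n, c, h, w = x.shape
        zh = x.mean(axis=3, keepdims=True)                    # (N, C, H, 1)
        zw = x.mean(axis=2, keepdims=True).transpose((0, 1, 3, 2))  # (N, C, W, 1)
        f = self.bn(self.conv1(nn.concat([zh, zw], axis=2)))
        f = nn.hardswish(f) if self.delta == "hardswish" else nn.sigmoid(f)
        fh = f[:, :, :h, :]
        fw = f[:, :, h:, :].transpose((0, 1, 3, 2))
        gh = nn.sigmoid(self.conv_h(fh))                      # (N, C, H, 1)
        gw = nn.sigmoid(self.conv_w(fw))                      # (N, C, 1, W)
        return gh, gw

    def forward(self, x: Tensor) -> Tensor:
        gh, gw = self.gates(x)
        return x * gh * gw
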