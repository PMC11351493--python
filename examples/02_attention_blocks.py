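"""The two attention operators and the SPPF-CA block on random features.

Runs LSKA against its full-2D LKA oracle on factored (rank-1) kernels, and
coordinate attention on a random feature map; prints the agreement and the
gate ranges.
"""

import numpy as np

from lesiondet.attention import (CAConfig, LSKAConfig, ca_forward, ca_gates,
                                 lka_forward, lska_forward)
from lesiondet.blocks import SPPFCA, sppf_ca_forward

rng = np.random.default_rng(0)

# LSKA vs LKA: when the 2D kernels factor into the 1D pairs, the separable
# cascade reproduces the full 2D depthwise attention exactly.
cfg = LSKAConfig.random(8, k=11, d=3, rng=rng)
x = rng.standard_normal((8, 16, 16))
w_local = cfg.v_local[:, :, None] * cfg.h_local[:, None, :]
w_dil = cfg.v_dil[:, :, None] * cfg.h_dil[:, None, :]
dev = np.abs(lska_forward(x, cfg) - lka_forward(x, w_local, w_dil, cfg.mix, cfg.d)).max()
print(f"LSKA vs full-2D LKA, rank-1 kernels: max |difference| = {dev:.2e}")

# Coordinate attention: per-row and per-column sigmoid gates.
ca = CAConfig.random(8, r=4, rng=rng)
gh, gw = ca_gates(x, ca)
y = ca_forward(x, ca)
print(f"CA gates: g_h in [{gh.min():.3f}, {gh.max():.3f}], "
      f"g_w in [{gw.min():.3f}, {gw.max():.3f}]; output shape {y.shape}")

# SPPF-CA: spatial pyramid with depthwise stages and CA gating.
block = SPPFCA(8, 8, rng=rng)
out = sppf_ca_forward(rng.standard_normal((8, 20, 20)), block)
print(f"SPPF-CA: 8x20x20 in -> {out.shape} out (shape-preserving pyramid)")
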