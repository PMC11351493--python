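"""Independent straight-line oracles used by the unit and acceptance tests.

These are deliberately naive transcriptions (explicit loops, scipy helpers)
kept separate from the package implementation so the two routes stay
independent.
"""

import numpy as np


def np_sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


def np_silu(v):
    return v * np_sigmoid(v)


def np_hardswish(v):
    return v * np.clip(v + 3.0, 0.0, 6.0) / 6.0


def dw_correlate_1d(x, taps, axis, dilation=1):
    """Per-channel 1-D correlation with zero padding, explicit loops."""
    c = x.shape[0]
    out = np.zeros_like(x)
    ln = taps.shape[1]
    half = (ln - 1) * dilation // 2
    for ch in range(c):
        plane = x[ch]
        acc = np.zeros_like(plane)
        for t in range(ln):
            off = t * dilation - half
            shifted = np.zeros_like(plane)
            if axis == "h":  # along width
                if off >= 0:
                    shifted[:, : plane.shape[1] - off] = plane[:, off:]
                else:
                    shifted[:, -off:] = plane[:, : plane.shape[1] + off]
            else:            # along height
                if off >= 0:
                    shifted[: plane.shape[0] - off, :] = plane[off:, :]
                else:
                    shifted[-off:, :] = plane[: plane.shape[0] + off, :]
            acc += taps[ch, t] * shifted
        out[ch] = acc
    return out


def conv_bn_silu_eval(x, conv, bn):
    """1×1 conv + eval-mode batch norm + SiLU, straight-line."""
    w = conv.weight.data[:, :, 0, 0]
    y = np.einsum("oc,chw->ohw", w, x)
    mu = bn.running_mean[:, None, None]
    sd = np.sqrt(bn.running_var + bn.eps)[:, None, None]
    y = (y - mu) / sd * bn.gamma.data[:, None, None] + bn.beta.data[:, None, None]
    return np_silu(y)


def coord_att_gates_eval(x, ca):
    """Eval-mode coordinate-attention gates from module weights, straight-line."""
    c, h, w = x.shape
    zh = x.mean(axis=2)                       # (C, H)
    zw = x.mean(axis=1)                       # (C, W)
    f = np.concatenate([zh, zw], axis=1)      # (C, H+W)
    w1 = ca.conv1.weight.data[:, :, 0, 0]
    f = w1 @ f + ca.conv1.bias.data[:, None]
    mu = ca.bn.running_mean[:, None]
    sd = np.sqrt(ca.bn.running_var + ca.bn.eps)[:, None]
    f = (f - mu) / sd * ca.bn.gamma.data[:, None] + ca.bn.beta.data[:, None]
    f = np_hardswish(f) if ca.delta == "hardswish" else np_sigmoid(f)
    fh, fw = f[:, :h], f[:, h:]
    wh = ca.conv_h.weight.data[:, :, 0, 0]
    ww = ca.conv_w.weight.data[:, :, 0, 0]
    gh = np_sigmoid(wh @ fh + ca.conv_h.bias.data[:, None])   # (C, H)
    gw = np_sigmoid(ww @ fw + ca.conv_w.bias.data[:, None])   # (C, W)
    return gh, gw


def sppf_ca_straightline(x, block):
    """Independent transcription of the SPPF-CA data flow in eval mode.

    Entry 1×1 → three separable 5-tap depthwise stages, each gated by the
    coordinate-attention gates of the preceding stage → concat of the four
    feature sets → exit 1×1.
    """
    f0 = conv_bn_silu_eval(x, block.cv1.conv, block.cv1.bn)
    feats = [f0]
    prev = f0
    for i in range(block.stages):
        hh = dw_correlate_1d(prev, block.dw_h[i].weight.data[:, 0, 0, :], "h")
        fi = dw_correlate_1d(hh, block.dw_v[i].weight.data[:, 0, :, 0], "v")
        gh, gw = coord_att_gates_eval(prev, block.ca[i])
        feats.append(fi * gh[:, :, None] * gw[:, None, :])
        prev = fi
    cat = np.concatenate(feats, axis=0)
    return conv_bn_silu_eval(cat, block.cv2.conv, block.cv2.bn)


def ap_by_cutoff_enumeration(confidences, tp_flags, num_gt):
    """AP via explicit enumeration of every confidence cutoff.

    At each cutoff keep detections with confidence ≥ cutoff, recompute
    precision/recall, then integrate the monotone precision envelope.
    """
    conf = np.asarray(confidences, float)
    tp = np.asarray(tp_flags, float)
    if num_gt == 0 or conf.size == 0:
        return 0.0
    points = []
    for cut in sorted(set(conf), reverse=True):
        keep = conf >= cut
        tps = tp[keep].sum()
        fps = (1.0 - tp[keep]).sum()
        points.append((tps / num_gt, tps / (tps + fps)))
    rec = np.array([0.0] + [p[0] for p in points] + [points[-1][0]])
    prec = np.array([1.0] + [p[1] for p in points] + [0.0])
    prec = np.maximum.accumulate(prec[::-1])[::-1]
    return float(np.sum(np.diff(rec) * prec[1:]))
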