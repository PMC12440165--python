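"""Straight-line reference implementations used as independent oracles.

Everything here is written with explicit loops and no layer abstractions, so
it shares no code path with the package implementation it checks.
"""

import numpy as np


def conv3x3_same(x_chw: np.ndarray, w: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """Plain cross-correlation, stride 1, zero 'same' padding; (C, H, W) input."""
    c_in, h, wd = x_chw.shape
    c_out = w.shape[0]
    xp = np.zeros((c_in, h + 2, wd + 2))
    xp[:, 1 : 1 + h, 1 : 1 + wd] = x_chw
    out = np.zeros((c_out, h, wd))
    for o in range(c_out):
        for i in range(h):
            for j in range(wd):
                acc = 0.0
                for c in range(c_in):
                    for ki in range(3):
                        for kj in range(3):
                            acc += xp[c, i + ki, j + kj] * w[o, c, ki, kj]
                out[o, i, j] = acc + (b[o] if b is not None else 0.0)
    return out


def conv1x1(x_chw: np.ndarray, w: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    c_out = w.shape[0]
    out = np.tensordot(w[:, :, 0, 0], x_chw, axes=(1, 0))
    if b is not None:
        out = out + b[:, None, None]
    return out.reshape(c_out, *x_chw.shape[1:])


def multiscale(feature_hwc: np.ndarray, block) -> np.ndarray:
    """Literal cascade: S1 = K1*F1, Si = Ki*(Fi + S_{i-1}); concat; 1x1 fuse."""
    x = np.transpose(feature_hwc, (2, 0, 1))  # C,H,W
    d4 = x.shape[0] // 4
    outputs = []
    for i in range(4):
        part = x[i * d4 : (i + 1) * d4]
        if i > 0:
            part = part + outputs[i - 1]
        conv = block.group_convs[i]
        outputs.append(conv3x3_same(part, conv.weight.data, conv.bias.data))
    cat = np.concatenate(outputs, axis=0)
    fused = conv1x1(cat, block.fuse_ms.weight.data, block.fuse_ms.bias.data)
    return np.transpose(fused, (1, 2, 0))


def sample_covariance(obs: np.ndarray) -> np.ndarray:
    """(m, k) observations -> k x k mean-centred covariance, divisor m - 1."""
    m, k = obs.shape
    mean = obs.mean(axis=0)
    cov = np.zeros((k, k))
    for row in obs:
        d = row - mean
        cov += np.outer(d, d)
    return cov / (m - 1)


def directional_covariances(fprime_hwc: np.ndarray, block):
    x = np.transpose(fprime_hwc, (2, 0, 1))  # C,H,W
    c, h, w = x.shape
    cfg = block.cfg
    # channel branch: 1x1 reduction, observations = spatial positions
    rd = conv1x1(x, block.reduce_d.weight.data, block.reduce_d.bias.data)
    obs_d = rd.reshape(cfg.reduced_channels, h * w).T
    # width branch: affine along the width axis, observations = (c, h)
    ww, wb = block.reduce_w.weight.data, block.reduce_w.bias.data
    rw = np.einsum("chw,wk->chk", x, ww) + wb
    obs_w = rw.reshape(c * h, cfg.reduced_width)
    # height branch: affine along the height axis, observations = (c, w)
    hw, hb = block.reduce_h.weight.data, block.reduce_h.bias.data
    rh = np.einsum("cwh,hk->cwk", np.transpose(x, (0, 2, 1)), hw) + hb
    obs_h = rh.reshape(c * w, cfg.reduced_height)
    return (
        sample_covariance(obs_w),
        sample_covariance(obs_h),
        sample_covariance(obs_d),
    )


def covariance_attention(cov: np.ndarray, head) -> np.ndarray:
    """Row-wise 1-D conv (same padding), row mean, affine, sigmoid."""
    k = cov.shape[0]
    kern = head.kernel.data[0, 0, 0]
    r = len(kern)
    pad = r // 2
    pooled = np.zeros(k)
    for i in range(k):
        row = np.zeros(k + 2 * pad)
        row[pad : pad + k] = cov[i]
        conv_row = np.array(
            [sum(kern[t] * row[j + t] for t in range(r)) for j in range(k)]
        )
        pooled[i] = conv_row.mean()
    z = pooled @ head.fc.weight.data + head.fc.bias.data
    return 1.0 / (1.0 + np.exp(-z))


def instance_standardize(feature_hwc: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Per-channel standardisation over the spatial positions of one sample."""
    out = np.empty_like(feature_hwc)
    for c in range(feature_hwc.shape[2]):
        plane = feature_hwc[:, :, c]
        out[:, :, c] = (plane - plane.mean()) / np.sqrt(
            ((plane - plane.mean()) ** 2).mean() + eps
        )
    return out


def mshop(feature_hwc: np.ndarray, block) -> np.ndarray:
    """Full multi-scale high-order transform, assembled step by step."""
    fprime = instance_standardize(multiscale(feature_hwc, block))
    cov_w, cov_h, cov_d = directional_covariances(fprime, block)
    lam_w = covariance_attention(cov_w, block.att_w)  # length W
    lam_h = covariance_attention(cov_h, block.att_h)  # length H
    lam_d = covariance_attention(cov_d, block.att_d)  # length C
    gated = (
        fprime * lam_w[None, :, None]
        + fprime * lam_d[None, None, :]
        + fprime * lam_h[:, None, None]
    )
    fused = conv1x1(
        np.transpose(gated, (2, 0, 1)),
        block.fuse_out.weight.data,
        block.fuse_out.bias.data,
    )
    return np.transpose(fused, (1, 2, 0)) + feature_hwc
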