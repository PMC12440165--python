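"""Multi-scale high-order pooling (MsHop) block and the residual feature extractor.

The MsHop block combines two ideas:

* a hierarchical multi-scale stage: the input feature map is split into four
  channel groups, each passed through its own 3x3 convolution, with every
  group (after the first) receiving the previous group's output additively —
  a Res2Net-style cascade that widens the receptive field inside one block;
* tri-directional second-order pooling: the fused map is reduced along each
  of the width / height / channel axes, a sample covariance matrix is formed
  per axis, and a row-wise convolution + affine + sigmoid head turns every
  covariance matrix into a gating vector that rescales the fused map along
  its own axis.

The gated maps are summed, fused by a 1x1 convolution, and added back to the
block input (a residual connection), so a zeroed fusion convolution makes the
block an exact identity.

Feature maps at the functional API are per-sample ``(H, W, C)`` arrays
(height x width x channels); batched processing happens internally in NCHW.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from ._autodiff import Tensor, concat, no_grad

__all__ = [
    "MsHopConfig",
    "BackboneConfig",
    "CovarianceAttention",
    "MsHopBlock",
    "FeatureExtractor",
    "build_feature_extractor",
    "hierarchical_multiscale",
    "directional_covariances",
    "covariance_attention",
    "mshop_block",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class MsHopConfig:
    """Reduced dimensions used for the covariance branches.

    All reduced dimensions must be >= 2 (a covariance over fewer than two
    variables is degenerate) and strictly smaller than the corresponding
    feature-map dimension.
    """

    reduced_width: int
    reduced_height: int
    reduced_channels: int
    rowconv_kernel: int = 3
    groups: int = 4

    @classmethod
    def for_shape(cls, height: int, width: int, channels: int, rowconv_kernel: int = 3):
        """Default reduction ratios: W/2, H/2, D/4 (rounded up, floor 2)."""
        return cls(
            reduced_width=max(2, math.ceil(width / 2)),
            reduced_height=max(2, math.ceil(height / 2)),
            reduced_channels=max(2, math.ceil(channels / 4)),
            rowconv_kernel=rowconv_kernel,
        )

    def validate(self, height: int, width: int, channels: int):
        if self.groups != 4:
            raise ConfigurationError("the multi-scale split uses exactly 4 groups")
        if channels % 4 != 0:
            raise ConfigurationError(f"channel count {channels} not divisible by 4")
        for name, red, full in (
            ("width", self.reduced_width, width),
            ("height", self.reduced_height, height),
            ("channels", self.reduced_channels, channels),
        ):
            if red < 2:
                raise ConfigurationError(f"reduced {name} {red} < 2: covariance undefined")
            if red >= full:
                raise ConfigurationError(
                    f"reduced {name} {red} must be strictly smaller than {full}"
                )


class CovarianceAttention(nn.Module):
    """Gating head: row-wise 1-D convolution over a covariance matrix,
    row pooling, affine map to the target axis length, then a sigmoid."""

    def __init__(self, side: int, target_len: int, kernel_size: int, rng):
        if target_len < 1:
            raise ConfigurationError("target_len must be >= 1")
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ConfigurationError("rowconv kernel size must be odd and >= 1")
        self.side = side
        self.target_len = target_len
        self.kernel_size = kernel_size
        self.kernel = nn.Parameter(
            nn.he_normal(rng, (1, 1, 1, kernel_size), kernel_size)
        )
        self.fc = nn.Linear(side, target_len, rng)

    def forward(self, C: Tensor) -> Tensor:
        """C: (n, k, k) batch of covariance matrices -> (n, target_len) in (0,1)."""
        n, k = C.shape[0], C.shape[1]
        rows = C.reshape(n * k, 1, 1, k)
        conv = rows.conv2d(
            self.kernel, bias=None, stride=1, padding=(0, self.kernel_size // 2)
        )
        pooled = conv.reshape(n, k, k).mean(axis=2)  # one statistic per row
        return self.fc(pooled).sigmoid()


class MsHopBlock(nn.Module):
    def __init__(self, channels: int, height: int, width: int, cfg: MsHopConfig, rng):
        cfg.validate(height, width, channels)
        self.cfg = cfg
        self.channels, self.height, self.width = channels, height, width
        d4 = channels // 4
        self.group_convs = [nn.Conv2d(d4, d4, 3, rng) for _ in range(4)]
        self.fuse_ms = nn.Conv2d(channels, channels, 1, rng)
        self.reduce_d = nn.Conv2d(channels, cfg.reduced_channels, 1, rng)
        self.reduce_w = nn.Linear(width, cfg.reduced_width, rng)
        self.reduce_h = nn.Linear(height, cfg.reduced_height, rng)
        r = cfg.rowconv_kernel
        self.att_w = CovarianceAttention(cfg.reduced_width, width, r, rng)
        self.att_h = CovarianceAttention(cfg.reduced_height, height, r, rng)
        self.att_d = CovarianceAttention(cfg.reduced_channels, channels, r, rng)
        self.fuse_out = nn.Conv2d(channels, channels, 1, rng)
        # zero-init the output fusion: the block starts as an exact identity
        # (residual attention convention), so inserting it never destabilises
        # a stage at initialisation
        self.fuse_out.weight.data[...] = 0.0
        self.fuse_out.bias.data[...] = 0.0

    # -- stages, NCHW tensors ------------------------------------------------
    def multiscale(self, x: Tensor) -> Tensor:
        d4 = self.channels // 4
        outputs = []
        for i in range(4):
            part = x[:, i * d4 : (i + 1) * d4]
            if i > 0:
                part = part + outputs[i - 1]
            outputs.append(self.group_convs[i](part))
        return self.fuse_ms(concat(outputs, axis=1))

    @staticmethod
    def instance_standardize(fp: Tensor, eps: float = 1e-5) -> Tensor:
        """Per-sample, per-channel standardisation over spatial positions.

        The cascaded convolutions amplify feature scale without bound, which
        saturates the covariance-attention sigmoids and lets this block's
        gradients dominate the global clipping budget; standardising the
        fused map (no batch statistics involved) keeps the second-order
        branch well-conditioned.  A zero map stays exactly zero.
        """
        mu = fp.mean(axis=(2, 3), keepdims=True)
        centred = fp - mu
        var = (centred * centred).mean(axis=(2, 3), keepdims=True)
        return centred / (var + eps).sqrt()

    @staticmethod
    def _cov(obs: Tensor) -> Tensor:
        """Sample covariance of (n, m, k) observations: mean-centred, /(m-1)."""
        m = obs.shape[1]
        centred = obs - obs.mean(axis=1, keepdims=True)
        return (centred.swapaxes(1, 2) @ centred) * (1.0 / (m - 1))

    def covariances(self, fp: Tensor):
        n, c, h, w = fp.shape
        # channel branch: each spatial position is one observation
        rd = self.reduce_d(fp)  # (n, D', h, w)
        obs_d = rd.reshape(n, self.cfg.reduced_channels, h * w).swapaxes(1, 2)
        # width branch: reduce width; each (height, channel) pair is one observation
        rw = self.reduce_w(fp)  # (n, c, h, W')
        obs_w = rw.reshape(n, c * h, self.cfg.reduced_width)
        # height branch: reduce height; each (width, channel) pair is one observation
        rh = self.reduce_h(fp.swapaxes(2, 3))  # (n, c, w, H')
        obs_h = rh.reshape(n, c * w, self.cfg.reduced_height)
        return self._cov(obs_w), self._cov(obs_h), self._cov(obs_d)

    def forward(self, x: Tensor) -> Tensor:
        if not np.all(np.isfinite(x.data)):
            raise ValueError("non-finite values in MsHop input")
        n, c, h, w = x.shape
        fp = self.instance_standardize(self.multiscale(x))
        cov_w, cov_h, cov_d = self.covariances(fp)
        lam_w = self.att_w(cov_w).reshape(n, 1, 1, w)
        lam_h = self.att_h(cov_h).reshape(n, 1, h, 1)
        lam_d = self.att_d(cov_d).reshape(n, c, 1, 1)
        gated = fp * lam_w + fp * lam_d + fp * lam_h
        return self.fuse_out(gated) + x


# -- functional per-sample API (numpy (H, W, C) arrays) -----------------------


def _to_nchw(feature_map: np.ndarray) -> Tensor:
    feature_map = np.asarray(feature_map, dtype=np.float64)
    if feature_map.ndim != 3:
        raise ValueError("feature map must be (H, W, C)")
    if not np.all(np.isfinite(feature_map)):
        raise ValueError("non-finite values in feature map")
    return Tensor(np.transpose(feature_map, (2, 0, 1))[None])


def _to_hwc(t: Tensor) -> np.ndarray:
    return np.transpose(t.data[0], (1, 2, 0))


def hierarchical_multiscale(feature_map: np.ndarray, block: MsHopBlock) -> np.ndarray:
    """Res2Net-style cascaded group convolutions plus 1x1 fusion."""
    x = _to_nchw(feature_map)
    if x.shape[1] % 4 != 0:
        raise ConfigurationError("channel count must be divisible by 4")
    with no_grad():
        return _to_hwc(block.multiscale(x))


def directional_covariances(feature_map: np.ndarray, block: MsHopBlock):
    """Return (C_W, C_H, C_D): per-axis sample covariances of reduced features."""
    x = _to_nchw(feature_map)
    with no_grad():
        cov_w, cov_h, cov_d = block.covariances(x)
    return cov_w.data[0], cov_h.data[0], cov_d.data[0]


def covariance_attention(cov: np.ndarray, head: CovarianceAttention) -> np.ndarray:
    """Gating vector in (0,1)^target_len from a square covariance matrix."""
    cov = np.asarray(cov, dtype=np.float64)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance matrix must be square")
    with no_grad():
        return head(Tensor(cov[None])).data[0]


def mshop_block(feature_map: np.ndarray, block: MsHopBlock) -> np.ndarray:
    """Full MsHop transform; output shape equals input shape."""
    x = _to_nchw(feature_map)
    with no_grad():
        return _to_hwc(block.forward(x))


# -- backbone -----------------------------------------------------------------


@dataclass
class BackboneConfig:
    architecture: str = "micro"  # micro | resnet18 | resnet50
    mshop_stages: tuple = (2, 3)
    input_size: int = 64
    in_channels: int = 1
    pretrained_init: bool = False
    embed_dim: int = 32
    rowconv_kernel: int = 3
    mshop: MsHopConfig | None = None  # None -> per-stage defaults

    def validate(self):
        if self.architecture not in ("micro", "resnet18", "resnet50"):
            raise ConfigurationError(f"unknown architecture {self.architecture!r}")
        if self.pretrained_init:
            raise ConfigurationError(
                "pretrained_init=True requires ImageNet weights, which are not "
                "bundled; set pretrained_init=false for fully offline operation"
            )


class ResidualBlock(nn.Module):
    def __init__(self, c_in: int, c_out: int, rng, stride: int = 1):
        self.conv1 = nn.Conv2d(c_in, c_out, 3, rng, stride=stride, bias=False)
        self.bn1 = nn.BatchNorm2d(c_out)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, rng, bias=False)
        self.bn2 = nn.BatchNorm2d(c_out)
        self.shortcut = (
            nn.Conv2d(c_in, c_out, 1, rng, stride=stride, padding=0)
            if (stride != 1 or c_in != c_out)
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        skip = x if self.shortcut is None else self.shortcut(x)
        return (out + skip).relu()


class BottleneckBlock(nn.Module):
    def __init__(self, c_in: int, c_mid: int, rng, stride: int = 1, expansion: int = 4):
        c_out = c_mid * expansion
        self.conv1 = nn.Conv2d(c_in, c_mid, 1, rng, padding=0, bias=False)
        self.bn1 = nn.BatchNorm2d(c_mid)
        self.conv2 = nn.Conv2d(c_mid, c_mid, 3, rng, stride=stride, bias=False)
        self.bn2 = nn.BatchNorm2d(c_mid)
        self.conv3 = nn.Conv2d(c_mid, c_out, 1, rng, padding=0, bias=False)
        self.bn3 = nn.BatchNorm2d(c_out)
        self.shortcut = (
            nn.Conv2d(c_in, c_out, 1, rng, stride=stride, padding=0)
            if (stride != 1 or c_in != c_out)
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        skip = x if self.shortcut is None else self.shortcut(x)
        return (out + skip).relu()


_PROFILES = {
    # (block type, blocks per stage, stage widths, stem width)
    "micro": ("basic", [1, 1, 1], [16, 32, 32], 16),
    "resnet18": ("basic", [2, 2, 2, 2], [64, 128, 256, 512], 64),
    "resnet50": ("bottleneck", [3, 4, 6, 3], [64, 128, 256, 512], 64),
}


class FeatureExtractor(nn.Module):
    """Residual convolutional encoder with MsHop blocks after chosen stages.

    Maps a batch of ``in_channels x input_size^2`` images to ``embed_dim``
    embeddings via global average pooling and a linear head.
    """

    def __init__(self, cfg: BackboneConfig, rng):
        cfg.validate()
        self.cfg = cfg
        block_kind, depths, widths, stem_w = _PROFILES[cfg.architecture]
        expansion = 4 if block_kind == "bottleneck" else 1
        size = cfg.input_size
        self.stem = nn.Conv2d(cfg.in_channels, stem_w, 3, rng, stride=2, bias=False)
        self.stem_bn = nn.BatchNorm2d(stem_w)
        size = math.ceil(size / 2)
        self.stages = []
        self.mshops = []
        self._stage_channels = []
        c_prev = stem_w
        for stage_idx, (depth, width) in enumerate(zip(depths, widths), start=1):
            blocks = []
            for b in range(depth):
                stride = 2 if b == 0 else 1
                if block_kind == "basic":
                    blocks.append(ResidualBlock(c_prev, width, rng, stride=stride))
                    c_prev = width
                else:
                    blocks.append(BottleneckBlock(c_prev, width, rng, stride=stride))
                    c_prev = width * expansion
                if stride == 2:
                    size = math.ceil(size / 2)
            self.stages.append(nn.Sequential(*blocks))
            self._stage_channels.append(c_prev)
            if stage_idx in cfg.mshop_stages:
                ms_cfg = cfg.mshop or MsHopConfig.for_shape(
                    size, size, c_prev, cfg.rowconv_kernel
                )
                self.mshops.append(MsHopBlock(c_prev, size, size, ms_cfg, rng))
            else:
                self.mshops.append(None)
        self.head = nn.Linear(sum(self._stage_channels), cfg.embed_dim, rng)
        self.out_spatial = size

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem_bn(self.stem(x)).relu()
        pooled = []
        for stage, mshop in zip(self.stages, self.mshops):
            x = stage(x)
            if mshop is not None:
                x = mshop(x)
            pooled.append(x.mean(axis=(2, 3)))
        return self.head(concat(pooled, axis=1))

    def embed(self, images: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Embeddings for a numpy batch (N, H, W) or (N, C, H, W).

        Runs in evaluation mode (running batch-norm statistics, no graph), so
        the result is deterministic and independent of batch composition.
        """
        images = np.asarray(images, dtype=self.stem.weight.data.dtype)
        if images.ndim == 3:
            images = images[:, None]
        was_training = self.training
        self.eval()
        try:
            chunks = []
            with no_grad():
                for start in range(0, len(images), batch_size):
                    chunks.append(self.forward(Tensor(images[start : start + batch_size])).data)
        finally:
            self.train(was_training)
        return np.concatenate(chunks, axis=0)


def build_feature_extractor(cfg: BackboneConfig, seed: int = 0) -> FeatureExtractor:
    rng = np.random.default_rng(seed)
    return FeatureExtractor(cfg, rng)
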