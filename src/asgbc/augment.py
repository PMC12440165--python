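"""Stochastic view generation for the self-supervised phase.

The default policy is a grayscale-safe composition motivated by B-mode
physics: random resized crop, horizontal flip, brightness/contrast jitter,
Gaussian blur, and multiplicative speckle jitter.  Every transform preserves
image size and the [0, 1] intensity range (values are clamped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

__all__ = ["AugmentationPolicy", "make_views"]


@dataclass
class AugmentationPolicy:
    crop_scale: tuple = (0.6, 1.0)  # area fraction of the random resized crop
    hflip_p: float = 0.5
    brightness: float = 0.2  # additive jitter, fraction of dynamic range
    contrast: float = 0.2  # multiplicative jitter around 1
    blur_sigma: tuple = (0.1, 1.0)
    speckle_jitter: float = 0.1  # std of the multiplicative speckle field

    @classmethod
    def identity(cls) -> "AugmentationPolicy":
        return cls(
            crop_scale=(1.0, 1.0),
            hflip_p=0.0,
            brightness=0.0,
            contrast=0.0,
            blur_sigma=(0.0, 0.0),
            speckle_jitter=0.0,
        )


def _augment_one(img: np.ndarray, policy: AugmentationPolicy, rng) -> np.ndarray:
    h, w = img.shape
    out = img
    # random resized crop (area-scale parameterisation)
    lo, hi = policy.crop_scale
    if hi < 1.0 or lo < 1.0:
        scale = rng.uniform(lo, hi)
        side_h = max(2, int(round(h * np.sqrt(scale))))
        side_w = max(2, int(round(w * np.sqrt(scale))))
        top = int(rng.integers(0, h - side_h + 1))
        left = int(rng.integers(0, w - side_w + 1))
        crop = out[top : top + side_h, left : left + side_w]
        if crop.shape != (h, w):
            out = resize(crop, (h, w), order=1, anti_aliasing=False, preserve_range=True)
        else:
            out = crop.copy()
    if policy.hflip_p > 0 and rng.random() < policy.hflip_p:
        out = out[:, ::-1]
    if policy.contrast > 0 or policy.brightness > 0:
        c = rng.uniform(1 - policy.contrast, 1 + policy.contrast)
        b = rng.uniform(-policy.brightness, policy.brightness)
        out = (out - 0.5) * c + 0.5 + b
    lo_s, hi_s = policy.blur_sigma
    if hi_s > 0:
        sigma = rng.uniform(lo_s, hi_s)
        if sigma > 0.05:
            out = gaussian_filter(out, sigma, mode="reflect")
    if policy.speckle_jitter > 0:
        shape_l = 1.0 / policy.speckle_jitter**2
        out = out * rng.gamma(shape_l, 1.0 / shape_l, size=out.shape)
    return np.clip(out, 0.0, 1.0)


def make_views(batch: np.ndarray, policy: AugmentationPolicy, seed: int):
    """Two independently augmented copies of ``batch`` (N, H, W).

    Deterministic given ``(seed, batch order)``.  An all-identity policy
    returns the input unchanged in both views.
    """
    batch = np.asarray(batch, dtype=np.float64)
    rng = np.random.default_rng(seed)
    view1 = np.stack([_augment_one(img, policy, rng) for img in batch])
    view2 = np.stack([_augment_one(img, policy, rng) for img in batch])
    return view1, view2
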