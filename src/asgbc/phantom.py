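"""Synthetic B-mode gallbladder phantom generator.

Renders grayscale ultrasound-like images: a smooth tissue background carrying
multiplicative speckle, a dark (anechoic) elliptical gallbladder lumen with an
echogenic wall, and class-dependent findings:

* ``normal`` — clean lumen, intact wall;
* ``benign`` — a smooth, sharply-marginated echogenic focus (polyp-like)
  inside the lumen;
* ``malignant`` — an irregular-margin, heterogeneous-texture mass with a
  disrupted wall segment, mirroring the clinical picture of masses that lack
  clear boundaries.

Anatomy (lumen geometry, wall thickness, lesion size and margin irregularity)
is drawn once per patient, so all of a patient's images share one anatomy and
one label; per-image randomness covers pose jitter and speckle.  All outputs
are pure functions of ``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomConfig",
    "CLASSES",
    "DEFAULT_LESION_PARAMS",
    "sample_patient_params",
    "render_phantom",
    "generate_arrays",
    "generate_dataset",
    "corrupt_noise",
]

CLASSES = ("normal", "benign", "malignant")

DEFAULT_LESION_PARAMS = {
    "normal": {
        "eccentricity": (0.55, 0.80),
        "wall_thickness": (0.05, 0.08),
        "echogenicity_offset": 0.0,
        "margin_irregularity": (0.0, 0.0),
    },
    "benign": {
        "eccentricity": (0.55, 0.80),
        "wall_thickness": (0.05, 0.08),
        "echogenicity_offset": 0.0,
        "margin_irregularity": (0.0, 0.04),
        "focus_radius": (0.35, 0.55),
        "focus_intensity": (0.80, 0.95),
    },
    "malignant": {
        "eccentricity": (0.55, 0.80),
        "wall_thickness": (0.05, 0.09),
        "echogenicity_offset": 0.03,
        "margin_irregularity": (0.30, 0.50),
        "mass_radius": (0.55, 0.85),
        "mass_intensity": (0.35, 0.48),
        "heterogeneity": (0.30, 0.40),
        "wall_gap": (1.5, 2.6),  # radians of disrupted wall arc
    },
}


@dataclass
class PhantomConfig:
    image_size: int = 64
    n_patients: int = 150
    images_per_patient: tuple = (2, 6)
    class_proportions: tuple = (0.344, 0.445, 0.211)
    speckle_scale: float = 0.25
    lesion_params: dict = field(default_factory=lambda: DEFAULT_LESION_PARAMS)
    seed: int = 0

    def __post_init__(self):
        props = tuple(float(p) for p in self.class_proportions)
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        lo, hi = self.images_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("invalid images_per_patient range")
        self.class_proportions = props

    def to_dict(self):
        return asdict(self)


def _uniform(rng, bounds):
    lo, hi = bounds
    return lo if lo == hi else rng.uniform(lo, hi)


def sample_patient_params(label: str, rng: np.random.Generator, lesion_params=None) -> dict:
    """Draw one patient's anatomy for the given class."""
    if label not in CLASSES:
        raise ValueError(f"unknown label {label!r}")
    lp = (lesion_params or DEFAULT_LESION_PARAMS)[label]
    params = {
        "label": label,
        "center": (rng.uniform(-0.05, 0.05), rng.uniform(-0.05, 0.05)),
        "semi_major": rng.uniform(0.54, 0.66),
        "eccentricity": _uniform(rng, lp["eccentricity"]),
        "angle": rng.uniform(-0.35, 0.35),
        "wall_thickness": _uniform(rng, lp["wall_thickness"]),
        "echogenicity_offset": lp["echogenicity_offset"],
        "margin_irregularity": _uniform(rng, lp["margin_irregularity"]),
    }
    if label == "benign":
        params["focus_radius"] = _uniform(rng, lp["focus_radius"])
        params["focus_intensity"] = _uniform(rng, lp["focus_intensity"])
        # focus sits well inside the lumen
        ang = rng.uniform(0, 2 * math.pi)
        params["focus_pos"] = (0.35 * math.cos(ang), 0.35 * math.sin(ang))
    if label == "malignant":
        params["mass_radius"] = _uniform(rng, lp["mass_radius"])
        params["mass_intensity"] = _uniform(rng, lp["mass_intensity"])
        params["heterogeneity"] = _uniform(rng, lp["heterogeneity"])
        params["wall_gap"] = _uniform(rng, lp["wall_gap"])
        ang = rng.uniform(0, 2 * math.pi)
        params["mass_dir"] = ang
        params["mass_pos"] = (0.30 * math.cos(ang), 0.30 * math.sin(ang))
        params["margin_harmonics"] = [
            (k, rng.uniform(0.4, 1.0), rng.uniform(0, 2 * math.pi)) for k in range(2, 7)
        ]
    return params


def _smooth_noise(rng, size, sigma):
    noise = rng.standard_normal((size, size))
    smoothed = gaussian_filter(noise, sigma, mode="reflect")
    sd = smoothed.std()
    return smoothed / sd if sd > 0 else smoothed


def render_phantom(
    label: str,
    patient_params: dict,
    seed: int,
    image_size: int = 64,
    speckle_scale: float = 0.25,
) -> np.ndarray:
    """Render one grayscale phantom in [0, 1] of shape (image_size, image_size)."""
    if label not in CLASSES:
        raise ValueError(f"unknown label {label!r}")
    p = patient_params
    rng = np.random.default_rng(seed)
    s = image_size
    ax = np.linspace(-1.0, 1.0, s)
    xx, yy = np.meshgrid(ax, ax)

    # per-image pose jitter on a fixed per-patient anatomy
    cx = p["center"][0] + rng.normal(0, 0.012)
    cy = p["center"][1] + rng.normal(0, 0.012)
    th = p["angle"] + rng.normal(0, 0.025)
    u = (xx - cx) * math.cos(th) + (yy - cy) * math.sin(th)
    v = -(xx - cx) * math.sin(th) + (yy - cy) * math.cos(th)
    a = p["semi_major"]
    b = a * p["eccentricity"]
    r_ell = np.sqrt((u / a) ** 2 + (v / b) ** 2)

    img = 0.52 + p["echogenicity_offset"] + 0.07 * _smooth_noise(rng, s, 6.0)

    tw = p["wall_thickness"]
    lumen = r_ell < 1.0
    wall = (r_ell >= 1.0) & (r_ell < 1.0 + tw / min(a, b))
    img[lumen] = 0.12 + 0.02 * rng.standard_normal(int(lumen.sum()))
    wall_level = 0.82

    if label == "malignant":
        # wall disruption: erase the wall arc facing the mass
        phi = np.arctan2(v, u)
        gap = np.abs(np.angle(np.exp(1j * (phi - p["mass_dir"])))) < p["wall_gap"] / 2
        wall = wall & ~gap
    img[wall] = wall_level + 0.03 * rng.standard_normal(int(wall.sum()))

    if label == "benign":
        fx, fy = p["focus_pos"]
        d = np.sqrt((u - fx * a) ** 2 + (v - fy * b) ** 2)
        focus = d < p["focus_radius"] * min(a, b)
        smooth_mask = gaussian_filter(focus.astype(float), 0.6)
        img = img * (1 - smooth_mask) + p["focus_intensity"] * smooth_mask
    elif label == "malignant":
        mx, my = p["mass_pos"]
        du, dv = u - mx * a, v - my * b
        d = np.sqrt(du**2 + dv**2)
        phi_m = np.arctan2(dv, du)
        modulation = np.ones_like(phi_m)
        for k, coef, phase in p["margin_harmonics"]:
            modulation += p["margin_irregularity"] * coef * np.cos(k * phi_m + phase)
        radius = p["mass_radius"] * min(a, b) * np.clip(modulation, 0.3, None)
        mass = d < radius
        texture = p["mass_intensity"] + p["heterogeneity"] * _smooth_noise(rng, s, 1.0)
        smooth_mask = gaussian_filter(mass.astype(float), 0.5)
        img = img * (1 - smooth_mask) + texture * smooth_mask

    # multiplicative speckle: gamma-distributed field with unit mean
    if speckle_scale > 0:
        shape_l = 1.0 / speckle_scale**2
        speckle = rng.gamma(shape_l, 1.0 / shape_l, size=(s, s))
        speckle = gaussian_filter(speckle, 0.6, mode="reflect")
        img = img * speckle
    return np.clip(img, 0.0, 1.0)


def _patient_labels(cfg: PhantomConfig, rng) -> list:
    """Largest-remainder allocation of patients to classes, then shuffled."""
    n = cfg.n_patients
    raw = [p * n for p in cfg.class_proportions]
    counts = [int(math.floor(r)) for r in raw]
    remainder_order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in range(n - sum(counts)):
        counts[remainder_order[i]] += 1
    labels = [CLASSES[i] for i, c in enumerate(counts) for _ in range(c)]
    rng.shuffle(labels)
    return labels


def generate_arrays(cfg: PhantomConfig):
    """In-memory dataset: (images (N, s, s), manifest DataFrame without paths).

    The manifest has columns ``patient_id`` and ``label``; row order matches
    the image stack.  Deterministic in ``cfg.seed``.
    """
    root = np.random.default_rng(cfg.seed)
    labels = _patient_labels(cfg, root)
    seed_seq = np.random.SeedSequence(cfg.seed)
    children = seed_seq.spawn(cfg.n_patients)
    images, rows = [], []
    lo, hi = cfg.images_per_patient
    for i, (label, child) in enumerate(zip(labels, children)):
        prng = np.random.default_rng(child)
        params = sample_patient_params(label, prng, cfg.lesion_params)
        n_images = int(prng.integers(lo, hi + 1))
        for j in range(n_images):
            img_seed = int(prng.integers(0, 2**31 - 1))
            images.append(
                render_phantom(
                    label, params, img_seed, cfg.image_size, cfg.speckle_scale
                )
            )
            rows.append({"patient_id": f"patient{i:03d}", "label": label, "image_index": j})
    manifest = pd.DataFrame(rows)
    return np.stack(images), manifest


def generate_dataset(cfg: PhantomConfig, out_dir) -> Path:
    """Write PNG images + ``manifest.csv`` (image_path, patient_id, label).

    Returns the manifest path.  Image paths are relative to the manifest.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    images, manifest = generate_arrays(cfg)
    paths = []
    for row, img in zip(manifest.itertuples(), images):
        name = f"images/{row.patient_id}_img{row.image_index}.png"
        arr = np.round(img * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out_dir / name)
        paths.append(name)
    out = pd.DataFrame(
        {"image_path": paths, "patient_id": manifest["patient_id"], "label": manifest["label"]}
    )
    manifest_path = out_dir / "manifest.csv"
    out.to_csv(manifest_path, index=False)
    return manifest_path


def corrupt_noise(image: np.ndarray, level: float, kernel_sigma: float = 5.0, seed=0):
    """Additive spatially-correlated Gaussian noise.

    A white Gaussian field is smoothed by a spatial Gaussian kernel of
    ``kernel_sigma`` pixels, rescaled so its standard deviation equals
    ``level`` times the format dynamic range (1.0 for [0, 1] images), added,
    and the result clamped back to [0, 1].
    """
    if level < 0:
        raise ValueError("noise level must be >= 0")
    image = np.asarray(image, dtype=np.float64)
    if level == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(image.shape)
    if kernel_sigma > 0:
        noise = gaussian_filter(noise, kernel_sigma, mode="reflect")
    sd = noise.std()
    if sd > 0:
        noise = noise * (level / sd)
    return np.clip(image + noise, 0.0, 1.0)
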