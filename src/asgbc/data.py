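"""Dataset I/O: manifest CSVs and grayscale image stacks.

The manifest schema is ``image_path,patient_id,label`` (UTF-8, header
required), with labels in {normal, benign, malignant}.  Image paths are
resolved relative to the manifest file.  The in-memory form keeps images as a
float stack in [0, 1] plus the manifest DataFrame, so synthetic benchmarks can
skip disk entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .phantom import CLASSES

__all__ = ["Dataset", "load_manifest", "encode_labels", "CLASSES"]

LABEL_TO_INT = {c: i for i, c in enumerate(CLASSES)}


def load_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"image_path", "patient_id"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    if "label" in df.columns:
        bad = set(df["label"].unique()) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown labels in manifest: {sorted(bad)}")
    return df


def encode_labels(labels) -> np.ndarray:
    try:
        return np.asarray([LABEL_TO_INT[l] for l in labels])
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}") from None


@dataclass
class Dataset:
    images: np.ndarray  # (N, H, W) float64 in [0, 1]
    manifest: pd.DataFrame  # patient_id [, label, image_path]

    def __post_init__(self):
        if len(self.images) != len(self.manifest):
            raise ValueError("image stack and manifest length differ")

    @property
    def has_labels(self) -> bool:
        return "label" in self.manifest.columns

    @property
    def labels(self) -> np.ndarray:
        if not self.has_labels:
            raise ValueError("manifest has no label column")
        return encode_labels(self.manifest["label"])

    @property
    def patient_ids(self) -> np.ndarray:
        return self.manifest["patient_id"].to_numpy()

    def without_labels(self) -> "Dataset":
        return Dataset(self.images, self.manifest.drop(columns=["label"], errors="ignore"))

    def subset(self, indices) -> "Dataset":
        indices = np.asarray(indices)
        return Dataset(self.images[indices], self.manifest.iloc[indices].reset_index(drop=True))

    @classmethod
    def from_manifest(cls, manifest_path, image_size: int | None = None) -> "Dataset":
        manifest_path = Path(manifest_path)
        df = load_manifest(manifest_path)
        base = manifest_path.parent
        images = []
        for rel in df["image_path"]:
            p = Path(rel)
            full = p if p.is_absolute() else base / p
            if not full.exists():
                raise FileNotFoundError(f"image not found: {full}")
            img = Image.open(full).convert("L")
            if image_size is not None and img.size != (image_size, image_size):
                img = img.resize((image_size, image_size), Image.BILINEAR)
            images.append(np.asarray(img, dtype=np.float64) / 255.0)
        return cls(np.stack(images), df)
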