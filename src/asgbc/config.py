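"""YAML round-trip for run and phantom configurations.

One YAML file carries sections {backbone, loss, active, train, augment,
holdout_fraction, seed}; hyperparameter defaults follow the reference training
recipe wherever it fixes a value (batch 64, lr 0.003, cosine schedule, lambda =
mu = 25, epsilon = 1e-4, alpha = 0.1, beta = lambda1 = lambda2 = 1).
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .active import ALConfig
from .augment import AugmentationPolicy
from .losses import LossWeights
from .mshop import BackboneConfig, MsHopConfig
from .phantom import PhantomConfig
from .pipeline import RunConfig, TrainConfig

__all__ = [
    "run_config_to_dict",
    "run_config_from_dict",
    "save_run_config",
    "load_run_config",
    "save_phantom_config",
    "load_phantom_config",
]


def run_config_to_dict(cfg: RunConfig) -> dict:
    return {
        "backbone": asdict(cfg.backbone),
        "loss": cfg.loss.to_dict(),
        "active": asdict(cfg.active),
        "train": asdict(cfg.train),
        "augment": asdict(cfg.augment),
        "holdout_fraction": cfg.holdout_fraction,
        "seed": cfg.seed,
    }


def run_config_from_dict(d: dict) -> RunConfig:
    backbone = dict(d.get("backbone", {}))
    mshop = backbone.pop("mshop", None)
    backbone["mshop_stages"] = tuple(backbone.get("mshop_stages", (2, 3)))
    bb = BackboneConfig(**backbone)
    if mshop is not None:
        bb.mshop = MsHopConfig(**mshop)
    active = dict(d.get("active", {}))
    if "budget_schedule" in active:
        active["budget_schedule"] = tuple(active["budget_schedule"])
    augment = dict(d.get("augment", {}))
    for key in ("crop_scale", "blur_sigma"):
        if key in augment:
            augment[key] = tuple(augment[key])
    return RunConfig(
        backbone=bb,
        loss=LossWeights(**d.get("loss", {})),
        active=ALConfig(**active),
        train=TrainConfig(**d.get("train", {})),
        augment=AugmentationPolicy(**augment),
        holdout_fraction=d.get("holdout_fraction", 0.25),
        seed=d.get("seed", 0),
    )


def save_run_config(cfg: RunConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(run_config_to_dict(cfg), fh, sort_keys=False)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        return run_config_from_dict(yaml.safe_load(fh))


def save_phantom_config(cfg: PhantomConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def load_phantom_config(path) -> PhantomConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    for key in ("images_per_patient", "class_proportions"):
        if key in d:
            d[key] = tuple(d[key])
    if "lesion_params" in d:
        d["lesion_params"] = {
            cls: {k: tuple(v) if isinstance(v, list) else v for k, v in params.items()}
            for cls, params in d["lesion_params"].items()
        }
    return PhantomConfig(**d)
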