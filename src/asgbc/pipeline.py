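"""Three-phase orchestration: select -> self-supervised pretrain -> linear probe.

Phase 1 (``asgbc.active``) chooses which samples deserve annotation; Phase 2
trains the MsHop residual extractor with the dual-branch objective on the
selected images only (no labels consumed); Phase 3 freezes the backbone and
fits a single affine classifier on the selected, now-labeled, embeddings.
Evaluation happens on a patient-grouped holdout that no phase ever saw.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from sklearn.model_selection import GroupShuffleSplit

from . import nn
from ._autodiff import Tensor, no_grad
from .active import ALConfig, DataPool, run_active_selection
from .augment import AugmentationPolicy, make_views
from .data import Dataset, encode_labels
from .evaluation import confusion_and_metrics
from .losses import Expander, LossWeights, PrototypeBank, clustering_loss, contrastive_loss
from .mshop import BackboneConfig, FeatureExtractor
from .phantom import CLASSES

__all__ = [
    "TrainConfig",
    "Checkpoint",
    "cosine_lr",
    "pretrain_extractor",
    "linear_probe",
    "ProbeClassifier",
    "run_asgbc",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = "asgbc-checkpoint-1"


@dataclass
class TrainConfig:
    iterations: int = 800  # optimizer steps for the self-supervised phase
    batch_size: int = 64
    lr: float = 0.003
    beta1: float = 0.9
    weight_decay: float = 1e-6
    schedule: str = "cosine"  # cosine | constant
    seed: int = 0
    deterministic: bool = True
    expander_hidden: int = 64
    expander_out: int = 64
    n_prototypes: int = 30
    probe_steps: int = 200
    probe_lr: float = 0.05
    warmup_iters: int = 10  # linear LR ramp before the decay schedule
    grad_clip: float = 10.0  # global grad-norm ceiling; 0 disables
    dtype: str = "float32"  # arithmetic precision of the training loop

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (variance terms undefined)")
        if self.iterations < 1 or self.lr <= 0:
            raise ValueError("iterations and lr must be positive")
        if self.schedule not in ("cosine", "constant"):
            raise ValueError(f"unknown schedule {self.schedule!r}")


def cosine_lr(step: int, total: int, lr0: float) -> float:
    """Cosine decay from lr0 at step 0 to 0 at the final step."""
    t = min(step, total) / max(total, 1)
    return lr0 * 0.5 * (1.0 + math.cos(math.pi * t))


@dataclass
class Checkpoint:
    """Serializable bundle of the self-supervised model and its provenance."""

    backbone_cfg: BackboneConfig
    loss_weights: LossWeights
    train_cfg: TrainConfig
    backbone_state: dict
    expander_state: dict
    prototype_state: dict
    optimizer_state: dict
    iteration: int
    seed: int
    version: str = CHECKPOINT_VERSION

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "backbone": asdict(self.backbone_cfg),
                "loss": self.loss_weights.to_dict(),
                "train": asdict(self.train_cfg),
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def recalibrate_batchnorm(model, images: np.ndarray, batch_size: int = 64):
    """Refresh batch-norm running statistics with clean (unaugmented) batches.

    Training batches are augmented and small, so the exponential running
    estimates can sit far from the statistics of the data the model is
    evaluated on; one pass over clean images re-anchors them.
    """
    bns = [m for m in model.modules() if isinstance(m, nn.BatchNorm)]
    if not bns:
        return
    for bn in bns:
        bn.running_mean[...] = 0.0
        bn.running_var[...] = 0.0
    was_training = model.training
    model.train(True)
    count = 0
    with no_grad():
        for start in range(0, len(images), batch_size):
            batch = images[start : start + batch_size]
            if len(batch) < 2:
                continue
            for bn in bns:
                bn.momentum = 1.0  # capture this batch's stats
            model(Tensor(batch[:, None]))
            # accumulate a running average over batches
            count += 1
            if count == 1:
                for bn in bns:
                    bn._acc_mean = bn.running_mean.copy()
                    bn._acc_var = bn.running_var.copy()
            else:
                for bn in bns:
                    bn._acc_mean += (bn.running_mean - bn._acc_mean) / count
                    bn._acc_var += (bn.running_var - bn._acc_var) / count
    for bn in bns:
        if hasattr(bn, "_acc_mean"):
            bn.running_mean[...] = bn._acc_mean
            bn.running_var[...] = bn._acc_var
            del bn._acc_mean, bn._acc_var
        bn.momentum = 0.1
    model.train(was_training)


def _build_models(backbone_cfg: BackboneConfig, train_cfg: TrainConfig, w: LossWeights):
    rng = np.random.default_rng(train_cfg.seed)
    backbone = FeatureExtractor(backbone_cfg, rng)
    expander = Expander(
        backbone_cfg.embed_dim, train_cfg.expander_hidden, train_cfg.expander_out, rng
    )
    prototypes = PrototypeBank(
        train_cfg.n_prototypes, backbone_cfg.embed_dim, rng, tau=w.tau
    )
    if train_cfg.dtype == "float32":
        for model in (backbone, expander, prototypes):
            model.astype(np.float32)
    return backbone, expander, prototypes


def restore_models(ckpt: Checkpoint):
    backbone, expander, prototypes = _build_models(
        ckpt.backbone_cfg, ckpt.train_cfg, ckpt.loss_weights
    )
    backbone.load_state_dict(ckpt.backbone_state)
    expander.load_state_dict(ckpt.expander_state)
    prototypes.load_state_dict(ckpt.prototype_state)
    return backbone, expander, prototypes


def pretrain_extractor(
    pool: DataPool,
    dataset: Dataset,
    backbone_cfg: BackboneConfig,
    loss_weights: LossWeights,
    train_cfg: TrainConfig,
    policy: AugmentationPolicy | None = None,
):
    """Phase 2: dual-branch self-supervised training on the selected pool.

    Labels are never read (only ``dataset.images`` is touched).  Returns
    ``(Checkpoint, logs)`` where logs carry per-iteration loss components.
    Diverging (non-finite) losses abort with the last finite-state checkpoint.
    """
    if not pool.selected:
        raise ValueError("selected pool is empty")
    policy = policy or AugmentationPolicy()
    dtype = np.float32 if train_cfg.dtype == "float32" else np.float64
    images = dataset.images[np.asarray(pool.selected)]
    backbone, expander, prototypes = _build_models(backbone_cfg, train_cfg, loss_weights)
    params = backbone.parameters() + expander.parameters() + prototypes.parameters()
    opt = nn.Adam(
        params, lr=train_cfg.lr, beta1=train_cfg.beta1, weight_decay=train_cfg.weight_decay
    )
    rng = np.random.default_rng(train_cfg.seed + 1)
    order = rng.permutation(len(images))
    cursor = 0
    logs = {"l_con": [], "l_clu": [], "l_total": [], "lr": []}
    last_good = None
    for it in range(train_cfg.iterations):
        take = min(train_cfg.batch_size, len(images))
        if cursor + take > len(order):  # reshuffle epoch boundary (no replacement)
            order = rng.permutation(len(images))
            cursor = 0
        idx = order[cursor : cursor + take]
        cursor += take
        view_seed = int(np.random.SeedSequence([train_cfg.seed, it]).generate_state(1)[0] % (2**31))
        x1, x2 = make_views(images[idx], policy, view_seed)
        # both views share one forward pass (and batch-norm statistics)
        both = Tensor(np.concatenate([x1, x2])[:, None].astype(dtype))
        yb = backbone(both)
        zb = expander(yb)
        y1, y2 = yb[:take], yb[take:]
        z1, z2 = zb[:take], zb[take:]
        l_con = contrastive_loss(z1, z2, loss_weights)
        if loss_weights.alpha:
            l_clu = clustering_loss(y1, y2, prototypes, loss_weights)
            loss = l_con + loss_weights.alpha * l_clu
            l_clu_val = float(l_clu.item())
        else:
            loss = l_con
            l_clu_val = 0.0
        if not np.isfinite(loss.item()):
            if last_good is None:
                raise FloatingPointError("loss diverged on the first iteration")
            ckpt, _ = last_good
            logs["aborted_at"] = it
            return ckpt, logs
        lr = (
            cosine_lr(it, train_cfg.iterations, train_cfg.lr)
            if train_cfg.schedule == "cosine"
            else train_cfg.lr
        )
        if train_cfg.warmup_iters and it < train_cfg.warmup_iters:
            lr *= (it + 1) / train_cfg.warmup_iters
        opt.lr = lr
        opt.zero_grad()
        loss.backward()
        if train_cfg.grad_clip:
            nn.clip_grad_norm(params, train_cfg.grad_clip)
        opt.step()
        logs["l_con"].append(float(l_con.item()))
        logs["l_clu"].append(l_clu_val)
        logs["l_total"].append(float(loss.item()))
        logs["lr"].append(lr)
        if it % 10 == 0 or it == train_cfg.iterations - 1:
            last_good = (
                Checkpoint(
                    backbone_cfg,
                    loss_weights,
                    train_cfg,
                    backbone.state_dict(),
                    expander.state_dict(),
                    prototypes.state_dict(),
                    opt.state_dict(),
                    iteration=it + 1,
                    seed=train_cfg.seed,
                ),
                it,
            )
    # anchor batch-norm statistics on clean selected images before freezing
    recalibrate_batchnorm(backbone, images.astype(dtype))
    final = Checkpoint(
        backbone_cfg,
        loss_weights,
        train_cfg,
        backbone.state_dict(),
        expander.state_dict(),
        prototypes.state_dict(),
        opt.state_dict(),
        iteration=train_cfg.iterations,
        seed=train_cfg.seed,
    )
    return final, logs


class ProbeClassifier:
    """Frozen backbone + single affine layer over embeddings (3 classes).

    Embeddings are standardised with statistics of the probe's training set
    before the affine map; the composition is still one affine classifier.
    """

    def __init__(self, backbone: FeatureExtractor, probe: nn.Linear,
                 feat_mean=None, feat_scale=None):
        self.backbone = backbone
        self.probe = probe
        self.feat_mean = feat_mean
        self.feat_scale = feat_scale

    def _standardize(self, embeddings: np.ndarray) -> np.ndarray:
        if self.feat_mean is None:
            return embeddings
        return (embeddings - self.feat_mean) / self.feat_scale

    def _logits(self, embeddings: np.ndarray) -> np.ndarray:
        with no_grad():
            return self.probe(Tensor(self._standardize(embeddings))).data

    def predict_embeddings(self, embeddings: np.ndarray) -> np.ndarray:
        return self._logits(embeddings).argmax(axis=1)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Class indices; logits are averaged over the horizontal-flip pair."""
        images = np.asarray(images, dtype=np.float64)
        logits = self._logits(self.backbone.embed(images))
        logits = logits + self._logits(self.backbone.embed(images[:, :, ::-1]))
        return logits.argmax(axis=1)

    def predict_labels(self, images: np.ndarray) -> list:
        return [CLASSES[i] for i in self.predict(images)]


def fit_linear_probe(embeddings: np.ndarray, y: np.ndarray, train_cfg: TrainConfig):
    """Fit one affine layer (cross-entropy, Adam) on standardised embeddings.

    Returns ``(probe, feat_mean, feat_scale)``.
    """
    embeddings = np.asarray(embeddings, dtype=np.float64)
    feat_mean = embeddings.mean(axis=0)
    feat_scale = embeddings.std(axis=0)
    feat_scale[feat_scale < 1e-8] = 1.0
    rng = np.random.default_rng(train_cfg.seed + 2)
    probe = nn.Linear(embeddings.shape[1], len(CLASSES), rng)
    opt = nn.Adam(probe.parameters(), lr=train_cfg.probe_lr, beta1=train_cfg.beta1)
    x = Tensor((embeddings - feat_mean) / feat_scale)
    onehot = np.eye(len(CLASSES))[np.asarray(y)]
    n = len(y)
    for _ in range(train_cfg.probe_steps):
        logits = probe(x)
        shift = logits - logits.data.max(axis=1, keepdims=True)
        logp = shift - shift.exp().sum(axis=1, keepdims=True).log()
        loss = -(Tensor(onehot) * logp).sum() / n
        opt.zero_grad()
        loss.backward()
        opt.step()
    return probe, feat_mean, feat_scale


def linear_probe(
    checkpoint: Checkpoint,
    pool: DataPool,
    dataset: Dataset,
    train_cfg: TrainConfig | None = None,
) -> ProbeClassifier:
    """Phase 3: fit the linear classifier on frozen selected-pool embeddings."""
    train_cfg = train_cfg or checkpoint.train_cfg
    if not dataset.has_labels:
        raise ValueError("linear probe requires labels on the selected samples")
    sel = np.asarray(pool.selected)
    if dataset.manifest["label"].iloc[sel].isna().any():
        raise ValueError("missing labels on selected samples")
    labels = dataset.labels
    backbone, _, _ = restore_models(checkpoint)
    backbone.freeze()
    embeddings = backbone.embed(dataset.images[sel])
    probe, feat_mean, feat_scale = fit_linear_probe(embeddings, labels[sel], train_cfg)
    return ProbeClassifier(backbone, probe, feat_mean, feat_scale)


# -- checkpoint serialization -------------------------------------------------


def save_checkpoint(ckpt: Checkpoint, path):
    """Single-file weight dictionary (.npz) + YAML config sidecar."""
    path = Path(path)
    arrays = {}
    for group, state in (
        ("backbone", ckpt.backbone_state),
        ("expander", ckpt.expander_state),
        ("prototypes", ckpt.prototype_state),
    ):
        for k, v in state.items():
            arrays[f"{group}::{k}"] = v
    np.savez(path, **arrays)
    meta = {
        "version": ckpt.version,
        "iteration": ckpt.iteration,
        "seed": ckpt.seed,
        "config_hash": ckpt.config_hash(),
        "backbone": asdict(ckpt.backbone_cfg),
        "loss": ckpt.loss_weights.to_dict(),
        "train": asdict(ckpt.train_cfg),
    }
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_checkpoint(path) -> Checkpoint:
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with open(npz_path.with_suffix(".yaml")) as fh:
        meta = yaml.safe_load(fh)
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta.get('version')!r}")
    data = np.load(npz_path)
    states = {"backbone": {}, "expander": {}, "prototypes": {}}
    for key in data.files:
        group, name = key.split("::", 1)
        states[group][name] = data[key]
    backbone_cfg = BackboneConfig(**{**meta["backbone"], "mshop_stages": tuple(meta["backbone"]["mshop_stages"])})
    if backbone_cfg.mshop is not None:
        from .mshop import MsHopConfig

        backbone_cfg.mshop = MsHopConfig(**meta["backbone"]["mshop"])
    return Checkpoint(
        backbone_cfg=backbone_cfg,
        loss_weights=LossWeights(**meta["loss"]),
        train_cfg=TrainConfig(**meta["train"]),
        backbone_state=states["backbone"],
        expander_state=states["expander"],
        prototype_state=states["prototypes"],
        optimizer_state={},
        iteration=meta["iteration"],
        seed=meta["seed"],
    )


# -- end-to-end ---------------------------------------------------------------


@dataclass
class RunConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    loss: LossWeights = field(default_factory=LossWeights)
    active: ALConfig = field(default_factory=ALConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    augment: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    holdout_fraction: float = 0.25
    seed: int = 0

    def reseed(self, seed: int) -> "RunConfig":
        import copy

        cfg = copy.deepcopy(self)
        cfg.seed = seed
        cfg.active.seed = seed
        cfg.train.seed = seed
        return cfg


def benchmark_config(seed: int = 0, iterations: int = 160, batch_size: int = 32) -> RunConfig:
    """Desk-scale study profile: micro backbone at 64 px, shortened schedule.

    The augmentation policy is tuned to the phantom generator: moderate crops
    and mild intensity jitter, so that lesion brightness — a diagnostic cue,
    not a nuisance factor — survives the invariance objective.
    """
    cfg = RunConfig(
        backbone=BackboneConfig(architecture="micro", input_size=64, embed_dim=32),
        loss=LossWeights(),
        active=ALConfig(epochs=2, budget_schedule=(0.15, 0.25, 0.35), seed=seed),
        train=TrainConfig(iterations=iterations, batch_size=batch_size, seed=seed),
        augment=AugmentationPolicy(crop_scale=(0.75, 1.0), brightness=0.08, contrast=0.1),
    )
    return cfg.reseed(seed)


def _grouped_holdout(patient_ids, holdout_fraction: float, seed: int):
    splitter = GroupShuffleSplit(n_splits=1, test_size=holdout_fraction, random_state=seed)
    train_idx, test_idx = next(splitter.split(patient_ids, groups=patient_ids))
    return np.sort(train_idx), np.sort(test_idx)


def run_asgbc(
    dataset: Dataset,
    config: RunConfig,
    out_dir=None,
    selection: str = "active",
):
    """Full pipeline on a labeled dataset; returns a results dict.

    ``selection`` is ``active`` (Phase 1 VAAL game), ``random`` (uniform
    sample at the same final budget; the ablation arm), or ``full`` (all
    training images are labeled-eligible).
    """
    if selection not in ("active", "random", "full"):
        raise ValueError(f"unknown selection mode {selection!r}")
    t0 = time.time()
    log_lines = []
    train_idx, test_idx = _grouped_holdout(
        dataset.patient_ids, config.holdout_fraction, config.seed
    )
    train_ds = dataset.subset(train_idx)
    test_ds = dataset.subset(test_idx)
    n_train = len(train_ds.images)
    final_budget = config.active.budget_schedule[-1]
    log_lines.append(f"split: {n_train} train / {len(test_ds.images)} test images")

    phase_name = "select"
    try:
        if selection == "active":
            pool, al_logs = run_active_selection(train_ds.images, config.active)
        elif selection == "random":
            rng = np.random.default_rng(config.active.seed)
            k = math.ceil(final_budget * n_train)
            chosen = sorted(int(i) for i in rng.choice(n_train, size=k, replace=False))
            pool = DataPool(chosen, [i for i in range(n_train) if i not in set(chosen)], n_train)
            al_logs = {"mode": "random", "seed": config.active.seed}
        else:
            pool = DataPool(list(range(n_train)), [], n_train)
            al_logs = {"mode": "full"}
        log_lines.append(f"selected {len(pool.selected)}/{n_train} images ({selection})")

        phase_name = "pretrain"
        ckpt, pre_logs = pretrain_extractor(
            pool, train_ds.without_labels(), config.backbone, config.loss, config.train,
            policy=config.augment,
        )
        phase_name = "probe"
        probe = linear_probe(ckpt, pool, train_ds, config.train)
        phase_name = "evaluate"
        y_pred = probe.predict(test_ds.images)
        cm, metrics = confusion_and_metrics(test_ds.labels, y_pred)
    except Exception as exc:
        raise RuntimeError(f"ASGBC pipeline failed in phase {phase_name!r}: {exc}") from exc

    result = {
        "selection": selection,
        "metrics": metrics,
        "confusion": cm,
        "pool": pool,
        "checkpoint": ckpt,
        "probe": probe,
        "pretrain_logs": pre_logs,
        "selection_logs": al_logs,
        "train_indices": train_idx,
        "test_indices": test_idx,
        "runtime_s": time.time() - t0,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pool.save(out_dir / "pool.json", extra={"selection": selection, "seed": config.seed})
        save_checkpoint(ckpt, out_dir / "checkpoint.npz")
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump({k: float(v) for k, v in metrics.items()}, fh, indent=2)
        log_lines.append(f"finished in {result['runtime_s']:.1f}s")
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return result
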