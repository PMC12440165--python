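"""Variational-adversarial active sample selection (Phase 1).

A beta-VAE learns a latent representation of all images (labeled-eligible and
not), while a discriminator is trained to tell the two pools apart in latent
space.  The VAE plays a minimax game against the discriminator, trying to make
every latent look like it came from the selected pool.  After training, the
unselected samples the discriminator scores *lowest* (least like the selected
pool) are acquired, up to each budget in the schedule.  The whole phase never
reads labels: it operates purely on image content.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from ._autodiff import Tensor, as_tensor, no_grad

__all__ = [
    "DataPool",
    "ALConfig",
    "ConvVAE",
    "Discriminator",
    "gaussian_kl",
    "vae_transductive_loss",
    "vae_adversarial_loss",
    "discriminator_loss",
    "combined_vae_loss",
    "select_informative",
    "run_active_selection",
]

_CLIP = 1e-12


@dataclass
class DataPool:
    """Partition of sample indices into selected (labeled-eligible) and not."""

    selected: list
    unselected: list
    universe_size: int

    def __post_init__(self):
        self.selected = [int(i) for i in self.selected]
        self.unselected = [int(i) for i in self.unselected]
        self.validate()

    def validate(self):
        s, u = set(self.selected), set(self.unselected)
        if s & u:
            raise ValueError("selected and unselected overlap")
        if s | u != set(range(self.universe_size)):
            raise ValueError("pool does not cover the sample universe")

    def acquire(self, indices):
        indices = [int(i) for i in indices]
        if not set(indices) <= set(self.unselected):
            raise ValueError("can only acquire currently unselected samples")
        self.selected = self.selected + indices
        remaining = set(indices)
        self.unselected = [i for i in self.unselected if i not in remaining]
        self.validate()

    def to_dict(self):
        return {
            "selected": list(self.selected),
            "unselected": list(self.unselected),
            "universe_size": self.universe_size,
        }

    def save(self, path, extra=None):
        payload = self.to_dict()
        if extra:
            payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["selected"], d["unselected"], d["universe_size"])


@dataclass
class ALConfig:
    latent_dim: int = 32
    beta: float = 1.0
    lam1: float = 1.0
    lam2: float = 1.0
    init_fraction: float = 0.05
    budget_schedule: tuple = (0.15, 0.25, 0.35)
    epochs: int = 3
    lr_vae: float = 1e-3
    lr_disc: float = 1e-3
    lr_task: float = 1e-3  # reserved for an optional auxiliary task learner
    batch_size: int = 32
    vae_input: int = 32
    dtype: str = "float32"  # arithmetic precision of the selection game
    seed: int = 0

    def __post_init__(self):
        schedule = tuple(float(b) for b in self.budget_schedule)
        if not schedule or any(b2 <= b1 for b1, b2 in zip(schedule, schedule[1:])):
            raise ValueError("budget schedule must be non-empty and strictly increasing")
        if not 0 < self.init_fraction < min(schedule) <= 1:
            raise ValueError("need 0 < init_fraction < min(schedule) <= 1")
        if max(schedule) > 1:
            raise ValueError("budget schedule exceeds 1.0")
        self.budget_schedule = schedule


class ConvVAE(nn.Module):
    """Small convolutional beta-VAE over grayscale images (square inputs)."""

    def __init__(self, cfg: ALConfig, rng):
        size = cfg.vae_input
        if size % 4 != 0:
            raise ValueError("vae_input must be divisible by 4")
        self.size = size
        self.latent_dim = cfg.latent_dim
        s4 = size // 4
        self.enc1 = nn.Conv2d(1, 8, 3, rng, stride=2)
        self.enc2 = nn.Conv2d(8, 16, 3, rng, stride=2)
        self.flat_dim = 16 * s4 * s4
        self.fc_mean = nn.Linear(self.flat_dim, cfg.latent_dim, rng)
        self.fc_logvar = nn.Linear(self.flat_dim, cfg.latent_dim, rng)
        self.fc_dec = nn.Linear(cfg.latent_dim, self.flat_dim, rng)
        self.dec1 = nn.Conv2d(16, 8, 3, rng)
        self.dec2 = nn.Conv2d(8, 1, 3, rng)
        self._s4 = s4

    def encode(self, x: Tensor):
        h = self.enc2(self.enc1(x).relu()).relu()
        h = h.reshape(h.shape[0], self.flat_dim)
        return self.fc_mean(h), self.fc_logvar(h)

    def decode(self, z: Tensor) -> Tensor:
        h = self.fc_dec(z).relu()
        h = h.reshape(h.shape[0], 16, self._s4, self._s4)
        h = self.dec1(h.upsample_nearest(2)).relu()
        return self.dec2(h.upsample_nearest(2)).sigmoid()

    def reparameterize(self, mean: Tensor, logvar: Tensor, rng) -> Tensor:
        noise = rng.standard_normal(mean.shape).astype(mean.data.dtype)
        return mean + (logvar * 0.5).exp() * noise


class Discriminator(nn.Module):
    """Three-layer MLP scoring latents as probability of 'selected pool'."""

    def __init__(self, latent_dim: int, rng, hidden: int = 64):
        self.fc1 = nn.Linear(latent_dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, hidden, rng)
        self.fc3 = nn.Linear(hidden, 1, rng)

    def forward(self, z: Tensor) -> Tensor:
        h = self.fc2(self.fc1(z).relu()).relu()
        return self.fc3(h).sigmoid().reshape(h.shape[0])


# -- losses -------------------------------------------------------------------


def gaussian_kl(mean, logvar):
    """KL(N(mean, exp(logvar)) || N(0, I)), summed over dims, batch-averaged."""
    m, lv = as_tensor(mean), as_tensor(logvar)
    n = m.shape[0]
    kl = 0.5 * ((m * m) + lv.exp() - 1.0 - lv).sum()
    return kl / n


def _recon_error(x: Tensor, x_hat: Tensor) -> Tensor:
    diff = x - x_hat
    return (diff * diff).sum() / x.shape[0]


def vae_transductive_loss(batch_s, batch_u, vae: ConvVAE, cfg: ALConfig, rng=None):
    """Reconstruction + beta*KL over both pools (Gaussian likelihood reading).

    Returns a tensor when used in training (rng supplied for reparameterised
    decoding); with rng=None the posterior mean is decoded, which keeps the
    loss deterministic for analysis.
    """
    was_numpy = not isinstance(batch_s, Tensor) and not isinstance(batch_u, Tensor)
    total = None
    for batch in (batch_s, batch_u):
        x = as_tensor(batch)
        if x.ndim == 3:
            x = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
        if x.shape[0] == 0:
            raise ValueError("empty batch in transductive loss")
        mean, logvar = vae.encode(x)
        z = vae.reparameterize(mean, logvar, rng) if rng is not None else mean
        x_hat = vae.decode(z)
        term = _recon_error(x, x_hat) + cfg.beta * gaussian_kl(mean, logvar)
        if not np.all(np.isfinite(term.data)):
            raise FloatingPointError("transductive loss diverged (non-finite term)")
        total = term if total is None else total + term
    return total.item() if was_numpy else total


def _clipped_log(scores) -> Tensor:
    t = as_tensor(scores)
    if np.any(t.data <= 0):
        warnings.warn("discriminator scores at 0 clipped to 1e-12", RuntimeWarning)
        t = t + _CLIP  # keeps gradient path while bounding away from log(0)
    return t.log()


def vae_adversarial_loss(d_scores_s, d_scores_u):
    """-mean log D(z_S) - mean log D(z_U): the VAE wants everything 'selected'."""
    was_numpy = not isinstance(d_scores_s, Tensor) and not isinstance(d_scores_u, Tensor)
    s, u = as_tensor(d_scores_s), as_tensor(d_scores_u)
    loss = -_clipped_log(s).mean() - _clipped_log(u).mean()
    return loss.item() if was_numpy else loss


def discriminator_loss(d_scores_s, d_scores_u):
    """-mean log D(z_S) - mean log(1 - D(z_U))."""
    was_numpy = not isinstance(d_scores_s, Tensor) and not isinstance(d_scores_u, Tensor)
    s, u = as_tensor(d_scores_s), as_tensor(d_scores_u)
    loss = -_clipped_log(s).mean() - _clipped_log(1.0 - u).mean()
    return loss.item() if was_numpy else loss


def combined_vae_loss(l_trd, l_adv, cfg: ALConfig):
    """lam1 * L_trd + lam2 * L_adv."""
    return cfg.lam1 * l_trd + cfg.lam2 * l_adv


def select_informative(d_scores_u, budget: int):
    """Bottom-``budget`` scores (lowest 'selected' probability = most novel).

    Ties break by ascending original index; the result is ordered by
    (score, index).
    """
    scores = np.asarray(d_scores_u, dtype=np.float64)
    if budget > scores.size:
        raise ValueError(f"budget {budget} exceeds pool size {scores.size}")
    if budget < 0:
        raise ValueError("budget must be >= 0")
    order = np.lexsort((np.arange(scores.size), scores))
    return [int(i) for i in order[:budget]]


# -- phase 1 driver -----------------------------------------------------------


def _resize_for_vae(images: np.ndarray, size: int) -> np.ndarray:
    """Down/upsample a square image stack to the VAE working resolution.

    Integer downsampling uses block averaging (deterministic, cheap); other
    ratios fall back to bilinear interpolation.
    """
    n, h, w = images.shape
    if h == size and w == size:
        return images
    if h == w and h % size == 0:
        f = h // size
        return images.reshape(n, size, f, size, f).mean(axis=(2, 4))
    from skimage.transform import resize

    return np.stack(
        [resize(im, (size, size), order=1, anti_aliasing=True, preserve_range=True)
         for im in images]
    )


def _paired_batches(idx_a, idx_b, batch_size, rng):
    """Shuffle both pools; the shorter pool cycles so batches stay paired."""
    a = rng.permutation(idx_a)
    b = rng.permutation(idx_b)
    steps = max(1, math.ceil(max(len(a), len(b)) / batch_size))
    for step in range(steps):
        pos = np.arange(step * batch_size, (step + 1) * batch_size)
        yield np.take(a, pos % len(a)), np.take(b, pos % len(b))


def run_active_selection(images: np.ndarray, cfg: ALConfig):
    """Run Phase 1 on a stack of images (N, H, W) in [0, 1].

    Initialises the selected pool with ceil(init_fraction * N) uniformly random
    samples, then for every budget in the schedule trains the VAE/discriminator
    game for ``cfg.epochs`` epochs and acquires the lowest-scoring unselected
    samples up to that budget.  Returns ``(DataPool, logs)``; labels are never
    consulted (the function does not even accept them).
    """
    images = np.asarray(images, dtype=np.float64)
    images = _resize_for_vae(images, cfg.vae_input)
    if cfg.dtype == "float32":
        images = images.astype(np.float32)
    n = images.shape[0]
    rng = np.random.default_rng(cfg.seed)
    n_init = math.ceil(cfg.init_fraction * n)
    init = sorted(int(i) for i in rng.choice(n, size=n_init, replace=False))
    pool = DataPool(init, [i for i in range(n) if i not in set(init)], n)

    vae = ConvVAE(cfg, rng)
    disc = Discriminator(cfg.latent_dim, rng)
    if cfg.dtype == "float32":
        vae.astype(np.float32)
        disc.astype(np.float32)
    opt_vae = nn.Adam(vae.parameters(), lr=cfg.lr_vae)
    opt_disc = nn.Adam(disc.parameters(), lr=cfg.lr_disc)

    logs = {"rounds": [], "seed": cfg.seed}
    for budget_fraction in cfg.budget_schedule:
        target = math.ceil(budget_fraction * n)
        round_log = {"budget_fraction": budget_fraction, "target": target, "losses": []}
        for _ in range(cfg.epochs):
            for idx_s, idx_u in _paired_batches(
                pool.selected, pool.unselected, cfg.batch_size, rng
            ):
                xs = Tensor(images[idx_s][:, None])
                xu = Tensor(images[idx_u][:, None])
                # VAE step: transductive + adversarial
                l_trd = vae_transductive_loss(xs, xu, vae, cfg, rng=rng)
                zs_mean, _ = vae.encode(xs)
                zu_mean, _ = vae.encode(xu)
                l_adv = vae_adversarial_loss(disc(zs_mean), disc(zu_mean))
                l_vae = combined_vae_loss(l_trd, l_adv, cfg)
                opt_vae.zero_grad()
                l_vae.backward()
                opt_vae.step()
                # Discriminator step on detached latents
                with no_grad():
                    zs_d, _ = vae.encode(xs)
                    zu_d, _ = vae.encode(xu)
                l_d = discriminator_loss(disc(Tensor(zs_d.data)), disc(Tensor(zu_d.data)))
                opt_disc.zero_grad()
                l_d.backward()
                opt_disc.step()
                round_log["losses"].append(
                    {"vae": float(l_vae.item()), "disc": float(l_d.item())}
                )
                # Algorithm step for the task learner T is a deliberate no-op:
                # phase 1 is label-free, so no supervised objective exists here.
        # acquisition on latent means (deterministic given weights)
        with no_grad():
            unsel = np.asarray(pool.unselected)
            means = []
            for start in range(0, len(unsel), 256):
                chunk = Tensor(images[unsel[start : start + 256]][:, None])
                mean, _ = vae.encode(chunk)
                means.append(disc(mean).data)
            scores = np.concatenate(means) if means else np.empty(0)
        need = target - len(pool.selected)
        if need > 0:
            picked_local = select_informative(scores, min(need, len(unsel)))
            picked = [int(unsel[i]) for i in picked_local]
            pool.acquire(picked)
            round_log["acquired"] = picked
            round_log["scores_mean"] = float(scores.mean()) if scores.size else None
        logs["rounds"].append(round_log)
    return pool, logs
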