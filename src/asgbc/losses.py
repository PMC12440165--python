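"""Dual-branch self-supervised objective.

Two branches share a pair of augmented views:

* a *contrastive* branch in the VICReg family — an invariance term pulling
  paired embeddings together, a hinge on per-dimension standard deviation
  keeping embeddings spread out, and a penalty on off-diagonal covariance
  decorrelating dimensions;
* a *clustering* branch in the SwAV family — batch features are softly
  assigned to learnable prototypes through entropically regularised optimal
  transport (Sinkhorn-Knopp over the transport polytope), and each view must
  predict the *other* view's assignment codes (swapped prediction).

The total objective is ``L_total = L_con + alpha * L_clu``.

Every function accepts either plain numpy arrays (returning Python floats,
convenient for analysis and testing) or autodiff tensors (returning tensors,
used in training).  Codes are always computed without gradient tracking.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import logsumexp

from . import nn
from ._autodiff import Tensor, as_tensor

__all__ = [
    "LossWeights",
    "Expander",
    "PrototypeBank",
    "expand",
    "invariance_term",
    "variance_term",
    "covariance_term",
    "contrastive_loss",
    "compute_codes",
    "clustering_loss",
    "total_loss",
]


@dataclass
class LossWeights:
    """Hyperparameters of the dual-branch objective.

    lam/mu weight the invariance and variance terms (25 each), nu the
    covariance term (1), gamma the std hinge target (1); eps_var stabilises
    the std, eps_ot is the optimal-transport smoothing temperature, alpha
    mixes the clustering branch into the total loss, tau is the softmax
    temperature of the prototype-matching probabilities.  ``sqrt_variance``
    selects the standard-deviation hinge (default); setting it to False uses
    the raw variance + eps reading instead.
    """

    lam: float = 25.0
    mu: float = 25.0
    nu: float = 1.0
    gamma: float = 1.0
    eps_var: float = 1e-4
    eps_ot: float = 1e-4
    alpha: float = 0.1
    sinkhorn_iters: int = 3
    tau: float = 0.1
    sqrt_variance: bool = True

    def __post_init__(self):
        for name in ("lam", "mu", "nu", "gamma", "eps_var", "eps_ot", "tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sinkhorn_iters < 1:
            raise ValueError("sinkhorn_iters must be >= 1")

    def to_dict(self):
        return asdict(self)


def _prep(*arrays):
    """Wrap numpy inputs as tensors; remember whether the caller used numpy."""
    was_numpy = all(not isinstance(a, Tensor) for a in arrays)
    tensors = []
    for a in arrays:
        t = as_tensor(a)
        if not np.all(np.isfinite(t.data)):
            raise ValueError("non-finite values in embedding batch")
        tensors.append(t)
    return tensors, was_numpy


def _ret(value: Tensor, was_numpy: bool):
    return value.item() if was_numpy else value


class Expander(nn.Module):
    """Three fully connected layers with ReLU between layers 1-2 and 2-3.

    The two hidden layers are batch-normalised (standard practice for
    expansion heads in variance-regularised self-supervision); set
    ``normalize=False`` for the bare affine chain.
    """

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng, normalize: bool = True):
        self.fc1 = nn.Linear(d_in, d_hidden, rng)
        self.fc2 = nn.Linear(d_hidden, d_hidden, rng)
        self.fc3 = nn.Linear(d_hidden, d_out, rng)
        self.bn1 = nn.BatchNorm1d(d_hidden) if normalize else None
        self.bn2 = nn.BatchNorm1d(d_hidden) if normalize else None

    def forward(self, y: Tensor) -> Tensor:
        h = self.fc1(y)
        if self.bn1 is not None:
            h = self.bn1(h)
        h = self.fc2(h.relu())
        if self.bn2 is not None:
            h = self.bn2(h)
        return self.fc3(h.relu())

    def parameter_count(self) -> int:
        return sum(p.size for p in self.parameters())


def expand(y, expander: Expander):
    """Apply the expander h_phi; numpy in -> numpy out."""
    (t,), was_numpy = _prep(y)
    out = expander(t)
    return out.data if was_numpy else out


class PrototypeBank(nn.Module):
    """K learnable prototype vectors; rows are unit-normalised on demand."""

    def __init__(self, n_prototypes: int, dim: int, rng, tau: float = 0.1):
        if tau <= 0:
            raise ValueError("tau must be positive")
        self.vectors = nn.Parameter(rng.normal(0, 1.0 / np.sqrt(dim), (n_prototypes, dim)))
        self.tau = tau

    @property
    def n_prototypes(self) -> int:
        return self.vectors.shape[0]

    def normalized(self) -> Tensor:
        return _row_normalize(self.vectors)


def _row_normalize(t: Tensor) -> Tensor:
    norms_sq = (t * t).sum(axis=1, keepdims=True)
    if np.any(norms_sq.data <= 0):
        raise ValueError("zero-norm row cannot be normalised")
    return t / norms_sq.sqrt()


# -- contrastive branch -------------------------------------------------------


def invariance_term(z1, z2):
    """(1/n) sum_i ||z1_i - z2_i||^2 — mean squared pair distance."""
    (t1, t2), was_numpy = _prep(z1, z2)
    if t1.shape != t2.shape:
        raise ValueError(f"shape mismatch {t1.shape} vs {t2.shape}")
    n = t1.shape[0]
    diff = t1 - t2
    return _ret((diff * diff).sum() / n, was_numpy)


def variance_term(z, w: LossWeights | None = None):
    """(1/d) sum_j hinge(gamma - std_j); std is the regularised column std."""
    w = w or LossWeights()
    (t,), was_numpy = _prep(z)
    n, d = t.shape
    if n < 2:
        raise ValueError("variance term requires n >= 2")
    centred = t - t.mean(axis=0, keepdims=True)
    var = (centred * centred).sum(axis=0) / (n - 1)
    spread = (var + w.eps_var).sqrt() if w.sqrt_variance else var + w.eps_var
    hinge = (as_tensor(np.full(d, w.gamma, dtype=t.data.dtype)) - spread).relu()
    return _ret(hinge.sum() / d, was_numpy)


def covariance_term(z):
    """(1/d) sum_{i != j} C(Z)_{ij}^2 with C the d x d sample covariance."""
    (t,), was_numpy = _prep(z)
    n, d = t.shape
    if n < 2:
        raise ValueError("covariance term requires n >= 2")
    centred = t - t.mean(axis=0, keepdims=True)
    cov = (centred.swapaxes(0, 1) @ centred) * (1.0 / (n - 1))
    sq = cov * cov
    off_diag = sq.sum() - (sq * np.eye(d, dtype=t.data.dtype)).sum()
    return _ret(off_diag / d, was_numpy)


def contrastive_loss(z1, z2, w: LossWeights | None = None):
    """VICReg-style combination: lam*s + mu*(v1+v2) + nu*(c1+c2)."""
    w = w or LossWeights()
    (t1, t2), was_numpy = _prep(z1, z2)
    if t1.shape != t2.shape:
        raise ValueError(f"shape mismatch {t1.shape} vs {t2.shape}")
    loss = (
        w.lam * invariance_term(t1, t2)
        + w.mu * (variance_term(t1, w) + variance_term(t2, w))
        + w.nu * (covariance_term(t1) + covariance_term(t2))
    )
    return _ret(loss, was_numpy)


# -- clustering branch --------------------------------------------------------


def compute_codes(scores: np.ndarray, w: LossWeights | None = None) -> np.ndarray:
    """Entropic optimal-transport assignment codes on the transport polytope.

    Sinkhorn-Knopp: Q proportional to exp(scores/eps_ot), alternately
    normalised toward uniform marginals (columns sum 1/K, rows sum 1/n),
    finishing with the row normalisation so row marginals are exact.
    Always computed on detached numpy data.
    """
    w = w or LossWeights()
    scores = np.asarray(scores.data if isinstance(scores, Tensor) else scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite scores")
    n, k = scores.shape
    # log-domain Sinkhorn: numerically exact normalisations even at the very
    # sharp default temperature (1e-4), where a naive exp underflows to zero
    log_q = scores / w.eps_ot
    log_q -= log_q.max()  # overflow guard; cancelled by the normalisations
    log_k, log_n = np.log(k), np.log(n)
    for _ in range(w.sinkhorn_iters):
        log_q -= logsumexp(log_q, axis=0, keepdims=True) + log_k  # cols -> 1/K
        log_q -= logsumexp(log_q, axis=1, keepdims=True) + log_n  # rows -> 1/n (last)
    return np.exp(log_q)


def _log_softmax(logits: Tensor) -> Tensor:
    shift = logits - logits.data.max(axis=1, keepdims=True)  # constant shift
    return shift - shift.exp().sum(axis=1, keepdims=True).log()


def _assignment_scores(y: Tensor, prototypes: PrototypeBank) -> Tensor:
    return _row_normalize(y) @ prototypes.normalized().swapaxes(0, 1)


def clustering_loss(y1, y2, prototypes: PrototypeBank, w: LossWeights | None = None):
    """Swapped-prediction loss: l(Y1, Q2) + l(Y2, Q1).

    l(Y, Q) is the per-sample-average cross-entropy between the (row-rescaled)
    codes and the temperature-softmax of cosine similarities to prototypes.
    """
    w = w or LossWeights()
    (t1, t2), was_numpy = _prep(y1, y2)
    s1 = _assignment_scores(t1, prototypes)
    s2 = _assignment_scores(t2, prototypes)
    q1 = compute_codes(s1.data, w)
    q2 = compute_codes(s2.data, w)
    loss = _swapped_side(s1, q2, prototypes.tau) + _swapped_side(s2, q1, prototypes.tau)
    return _ret(loss, was_numpy)


def _swapped_side(scores: Tensor, codes: np.ndarray, tau: float) -> Tensor:
    n = scores.shape[0]
    q_tilde = (n * codes).astype(scores.data.dtype)  # rows rescaled to sum to 1
    logp = _log_softmax(scores / tau)
    return -(as_tensor(q_tilde) * logp).sum() / n


def total_loss(y1, y2, z1, z2, prototypes: PrototypeBank, w: LossWeights | None = None):
    """L_total = L_con(Z1, Z2) + alpha * L_clu(Y1, Y2)."""
    w = w or LossWeights()
    (ty1, ty2, tz1, tz2), was_numpy = _prep(y1, y2, z1, z2)
    loss = contrastive_loss(tz1, tz2, w)
    if w.alpha:
        loss = loss + w.alpha * clustering_loss(ty1, ty2, prototypes, w)
    return _ret(loss, was_numpy)
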