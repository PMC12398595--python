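"""Loss terms of the enhanced semi-supervised GAN.

Discriminator objective
    L_D = L_sup + L_usup + λ_consistency·L_consistency + λ_pseudo·L_pseudo

Generator objective
    L_G = L_adv + λ_r·L_r

with
    L_sup          = −E_{(x,y) labeled} log p(ŷ = y | x)
    L_usup         = −E_{x real} log(1 − p_fake(x)) − E_{x fake} log p_fake(x)
    L_adv          = −E_{x fake} log(1 − p_fake(x))
    L_r            = E_x ‖G(D_F(x)) − x‖₂
    L_consistency  = E_x ‖p(·|x) − p(·|x̃)‖²
    L_pseudo       = −E_{x unlabeled, conf ≥ τ} log p(ŷ_pseudo | x)

Probability columns follow the dataset label convention:
column 0 = non-melanoma, column 1 = melanoma, column 2 = fake.
Pseudo-labels are restricted to the two real classes (a "fake"
pseudo-label for a real image is meaningless).  Probabilities are
clamped to [ε, 1−ε], ε = 1e−7, before logarithms, since the losses are
undefined at exactly 0 or 1.

Setting (λ_r, attention, λ_consistency, λ_pseudo) to zero recovers the
conventional SS-GAN objective exactly — the ablation variants are pure
configuration, with no code forks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import CLASS_FAKE

EPS = 1e-7

__all__ = [
    "EPS",
    "LossWeights",
    "d_supervised_loss",
    "d_unsupervised_loss",
    "g_adversarial_loss",
    "reconstruction_loss",
    "g_total_loss",
    "consistency_loss",
    "pseudo_label_loss",
    "d_total_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """Weights of the auxiliary loss terms and the confidence threshold τ."""

    lambda_r: float = 0.42
    lambda_consistency: float = 0.28
    lambda_pseudo: float = 0.41
    tau: float = 0.9

    def __post_init__(self):
        for name in ("lambda_r", "lambda_consistency", "lambda_pseudo"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not 0.0 < self.tau <= 1.0:
            raise ValueError("tau must lie in (0, 1]")


def _check_probs(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValueError(f"{name} must be an m × 3 probability matrix")
    return p


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS, 1.0 - EPS)


def d_supervised_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true real class (labeled rows)."""
    probs = _check_probs(probs, "probs")
    labels = np.asarray(labels)
    if labels.shape != (probs.shape[0],):
        raise ValueError("labels must align with probability rows")
    if (labels == -1).any():
        raise ValueError("d_supervised_loss is a labeled-only contract; got -1")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must lie in {0, 1}")
    p_true = probs[np.arange(len(labels)), labels.astype(int)]
    return float(-np.mean(np.log(_clamp(p_true))))


def d_unsupervised_loss(probs_real: np.ndarray, probs_fake: np.ndarray) -> float:
    """−E_real log(1 − p_fake) − E_fake log p_fake (empty sides contribute 0)."""
    probs_real = _check_probs(np.asarray(probs_real).reshape(-1, 3), "probs_real")
    probs_fake = _check_probs(np.asarray(probs_fake).reshape(-1, 3), "probs_fake")
    if probs_real.shape[0] == 0 and probs_fake.shape[0] == 0:
        raise ValueError("d_unsupervised_loss needs at least one row")
    total = 0.0
    if probs_real.shape[0]:
        total -= float(np.mean(np.log(_clamp(1.0 - probs_real[:, CLASS_FAKE]))))
    if probs_fake.shape[0]:
        total -= float(np.mean(np.log(_clamp(probs_fake[:, CLASS_FAKE]))))
    return total


def g_adversarial_loss(probs_fake: np.ndarray) -> float:
    """−E_fake log(1 − p_fake): the generator wants fakes off the fake class."""
    probs_fake = _check_probs(probs_fake, "probs_fake")
    if probs_fake.shape[0] == 0:
        raise ValueError("g_adversarial_loss needs at least one row")
    return float(-np.mean(np.log(_clamp(1.0 - probs_fake[:, CLASS_FAKE]))))


def reconstruction_loss(x: np.ndarray, x_rec: np.ndarray) -> float:
    """Mean per-row Euclidean norm ‖x_rec − x‖₂."""
    x = np.asarray(x, dtype=np.float64)
    x_rec = np.asarray(x_rec, dtype=np.float64)
    if x.shape != x_rec.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_rec.shape}")
    return float(np.mean(np.linalg.norm(x_rec - x, axis=-1)))


def g_total_loss(adv: float, rec: float, w: LossWeights) -> float:
    if not (np.isfinite(adv) and np.isfinite(rec)):
        raise ValueError("loss terms must be finite")
    return float(adv + w.lambda_r * rec)


def consistency_loss(probs: np.ndarray, probs_aug: np.ndarray) -> float:
    """Mean squared Euclidean distance between paired probability rows."""
    probs = _check_probs(probs, "probs")
    probs_aug = _check_probs(probs_aug, "probs_aug")
    if probs.shape != probs_aug.shape:
        raise ValueError("probs and probs_aug must pair row-for-row")
    return float(np.mean(np.sum((probs - probs_aug) ** 2, axis=-1)))


def pseudo_label_loss(probs: np.ndarray, tau: float) -> tuple[float, int]:
    """Confidence-thresholded pseudo-labeling on unlabeled rows.

    The pseudo-label is the argmax over the two real classes; a row is
    selected iff its best real-class probability is ≥ τ.  Returns
    (0.0, 0) when nothing passes the threshold.
    """
    probs = _check_probs(probs, "probs")
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must lie in (0, 1]")
    real = probs[:, :CLASS_FAKE]
    conf = real.max(axis=-1) if len(real) else np.empty(0)
    selected = conf >= tau
    n_selected = int(selected.sum())
    if n_selected == 0:
        return 0.0, 0
    loss = float(-np.mean(np.log(_clamp(conf[selected]))))
    return loss, n_selected


def d_total_loss(sup: float, usup: float, cons: float, pseudo: float,
                 w: LossWeights) -> float:
    terms = (sup, usup, cons, pseudo)
    if not all(np.isfinite(t) for t in terms):
        raise ValueError("loss terms must be finite")
    return float(sup + usup + w.lambda_consistency * cons + w.lambda_pseudo * pseudo)
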