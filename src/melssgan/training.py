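"""Alternating SS-GAN training with masking, augmentation and pseudo-labels.

Each minibatch takes one discriminator step followed by one generator
step.  The discriminator minimises

    L_D = L_sup + L_usup + λ_c·L_consistency + λ_p·L_pseudo

where labeled rows feed the supervised term; *unlabeled* real rows enter
the first unsupervised term only while the discriminator currently
classifies them as fake (a stop-gradient indicator recomputed from the
live predictions each step); generated rows feed the second unsupervised
term; the consistency term pairs every real row with a Gaussian-noise
augmented copy of itself; and the pseudo-label term uses unlabeled rows
whose best real-class confidence reaches τ.  The generator minimises

    L_G = L_adv + λ_r·‖G(D_F(x)) − x‖₂

with the reconstruction pairs drawn from the same real minibatch.
Optimisation is Adam for both networks; after training the generator is
discarded and the discriminator serves as the classifier (argmax over
the two real classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, constant
from .data import FeatureDataset, UNLABELED
from .losses import EPS, LossWeights
from .networks import (
    CLASS_FAKE,
    CLASS_MELANOMA,
    CLASS_NON_MELANOMA,
    DiscriminatorNet,
    GeneratorNet,
    MLPSpec,
)

__all__ = ["TrainingConfig", "HistoryRecord", "train_ssgan", "predict", "Adam"]


@dataclass(frozen=True)
class TrainingConfig:
    """Training hyperparameters, validated against the search ranges."""

    batch_size: int = 64
    epochs: int = 64
    lr_g: float = 1e-3
    lr_d: float = 1e-3
    noise_size: int = 16
    g_spec: MLPSpec = field(default_factory=MLPSpec)
    d_spec: MLPSpec = field(default_factory=MLPSpec)
    weights: LossWeights = field(default_factory=LossWeights)
    aug_sigma: float = 0.1
    seed: int = 0
    use_attention: bool = True
    val_fraction: float = 0.2

    def __post_init__(self):
        if not 16 <= self.batch_size <= 512:
            raise ValueError("batch_size must lie in [16, 512]")
        if not 64 <= self.epochs <= 1024:
            raise ValueError("epochs must lie in [64, 1024]")
        for name in ("lr_g", "lr_d"):
            lr = getattr(self, name)
            if not 0.0 < lr < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 16 <= self.noise_size <= 1024:
            raise ValueError("noise_size must lie in [16, 1024]")
        if self.aug_sigma < 0:
            raise ValueError("aug_sigma must be >= 0")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in [0, 1)")


@dataclass
class HistoryRecord:
    epoch: int
    loss_g: float
    loss_d: float
    loss_sup: float
    loss_usup: float
    loss_cons: float
    loss_pseudo: float
    loss_adv: float
    loss_rec: float
    n_pseudo: int
    val_metrics: "object | None" = None


class Adam:
    """Adaptive-moment gradient descent over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            p.value = p.value - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _check_finite(value: float, term: str) -> float:
    if not np.isfinite(value):
        raise RuntimeError(f"training diverged: non-finite {term} loss")
    return float(value)


def _col(probs: Tensor, index: int) -> Tensor:
    basis = np.zeros((3, 1))
    basis[index, 0] = 1.0
    return probs @ constant(basis)  # (m, 1)


def _masked_mean(per_row: Tensor, mask: np.ndarray) -> Tensor:
    n = max(int(mask.sum()), 1)
    return (per_row * constant(mask.reshape(-1, 1))).sum() / float(n)


def _carve_validation(data: FeatureDataset, val_fraction: float, rng):
    """Stratified validation subset from the labeled rows."""
    if data.split is not None:
        val_idx = np.flatnonzero(data.split == "val")
        train_idx = np.flatnonzero(data.split != "val")
        return train_idx, val_idx
    if val_fraction <= 0:
        return np.arange(data.n), np.empty(0, dtype=int)
    val_mask = np.zeros(data.n, dtype=bool)
    for cls in (0, 1):
        idx = np.flatnonzero(data.labels == cls)
        n_val = max(1, int(round(val_fraction * len(idx)))) if len(idx) else 0
        if n_val and n_val < len(idx):
            val_mask[rng.choice(idx, size=n_val, replace=False)] = True
    return np.flatnonzero(~val_mask), np.flatnonzero(val_mask)


def train_ssgan(data: FeatureDataset, config: TrainingConfig):
    """Train the SS-GAN; returns (generator, discriminator, history)."""
    labeled = data.labels != UNLABELED
    for cls in (0, 1):
        if not (data.labels == cls).any():
            raise ValueError("training needs at least one labeled row per class")

    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31, size=6)
    rng_init_g, rng_init_d = int(seeds[0]), int(seeds[1])
    rng_data = np.random.default_rng(int(seeds[2]))
    rng_noise = np.random.default_rng(int(seeds[3]))
    rng_drop = np.random.default_rng(int(seeds[4]))
    rng_aug = np.random.default_rng(int(seeds[5]))

    train_idx, val_idx = _carve_validation(data, config.val_fraction, rng_data)
    X = data.features[train_idx]
    y = data.labels[train_idx]
    X_val = data.features[val_idx]
    y_val = data.labels[val_idx]

    gen = GeneratorNet(config.noise_size, data.d, config.g_spec,
                       seed=rng_init_g, use_attention=config.use_attention)
    dsc = DiscriminatorNet(data.d, config.noise_size, config.d_spec,
                           seed=rng_init_d, use_attention=config.use_attention)
    opt_g = Adam(gen.trainable(), config.lr_g)
    opt_d = Adam(dsc.trainable(), config.lr_d)
    w = config.weights
    n = X.shape[0]
    batch = min(config.batch_size, n)
    history: list[HistoryRecord] = []

    for epoch in range(config.epochs):
        order = rng_data.permutation(n)
        sums = np.zeros(8)
        n_pseudo_epoch = 0
        n_batches = 0
        for start in range(0, n, batch):
            rows = order[start:start + batch]
            if len(rows) < 2:
                continue
            Xb, yb = X[rows], y[rows]
            lab_mask = (yb != UNLABELED).astype(float)
            unlab_mask = 1.0 - lab_mask
            m = len(rows)

            # ---- discriminator step -----------------------------------
            z = rng_noise.standard_normal((m, config.noise_size))
            fake_X = constant(gen.forward_t(constant(z)).value)

            Xb_t = constant(Xb)
            probs = dsc.forward_t(Xb_t, True, rng_drop).clamp(EPS, 1.0 - EPS)
            probs_fake = dsc.forward_t(fake_X, True, rng_drop).clamp(EPS, 1.0 - EPS)

            onehot = np.zeros((m, 3))
            lab_rows = yb != UNLABELED
            onehot[np.flatnonzero(lab_rows), yb[lab_rows]] = 1.0
            p_true = (probs * constant(onehot)).sum(axis=1, keepdims=True)
            # log of unselected rows is masked out; clamp keeps it finite
            sup = _masked_mean(-(p_true.clamp(EPS, 1.0).log()), lab_mask)

            # masking rule: unlabeled real rows count only while the model
            # currently classifies them into the fake class
            pred_now = np.argmax(probs.value, axis=1)
            usup_real_mask = unlab_mask * (pred_now == CLASS_FAKE)
            p_fake_real = _col(probs, CLASS_FAKE)
            usup_real = (
                _masked_mean(-( (1.0 - p_fake_real).clamp(EPS, 1.0).log()), usup_real_mask)
                if usup_real_mask.sum() else constant(0.0)
            )
            usup_fake = -(_col(probs_fake, CLASS_FAKE).log()).mean()
            usup = usup_real + usup_fake

            if w.lambda_consistency > 0:
                X_aug = Xb + config.aug_sigma * rng_aug.standard_normal(Xb.shape)
                probs_aug = dsc.forward_t(constant(X_aug), True, rng_drop)
                cons = (probs - probs_aug).square().sum(axis=1).mean()
            else:
                cons = constant(0.0)

            if w.lambda_pseudo > 0 and unlab_mask.sum():
                real_probs = probs.value[:, :CLASS_FAKE]
                conf = real_probs.max(axis=1)
                pseudo_sel = unlab_mask * (conf >= w.tau)
                n_sel = int(pseudo_sel.sum())
                if n_sel:
                    pseudo_onehot = np.zeros((m, 3))
                    pseudo_onehot[np.arange(m), real_probs.argmax(axis=1)] = 1.0
                    p_pseudo = (probs * constant(pseudo_onehot)).sum(axis=1, keepdims=True)
                    pseudo = _masked_mean(-(p_pseudo.clamp(EPS, 1.0).log()), pseudo_sel)
                else:
                    pseudo = constant(0.0)
            else:
                n_sel = 0
                pseudo = constant(0.0)
            n_pseudo_epoch += n_sel

            loss_d = sup + usup + w.lambda_consistency * cons + w.lambda_pseudo * pseudo
            for term, name in ((sup, "supervised"), (usup, "unsupervised"),
                               (cons, "consistency"), (pseudo, "pseudo-label")):
                _check_finite(float(term.value), name)
            loss_d.backward()
            opt_d.step()

            # ---- generator step ---------------------------------------
            z2 = rng_noise.standard_normal((m, config.noise_size))
            gen_out = gen.forward_t(constant(z2), True, rng_drop)
            probs_g = dsc.forward_t(gen_out).clamp(EPS, 1.0 - EPS)
            adv = -((1.0 - _col(probs_g, CLASS_FAKE)).clamp(EPS, 1.0).log()).mean()

            if w.lambda_r > 0:
                feats = dsc.features(Xb)  # constant w.r.t. generator params
                rec_out = gen.forward_t(constant(feats), True, rng_drop)
                rec = (rec_out - Xb_t).row_l2().mean()
            else:
                rec = constant(0.0)
            loss_g = adv + w.lambda_r * rec
            _check_finite(float(adv.value), "adversarial")
            _check_finite(float(rec.value), "reconstruction")
            loss_g.backward()
            opt_g.step()

            sums += [float(loss_d.value), float(loss_g.value), float(sup.value),
                     float(usup.value), float(cons.value), float(pseudo.value),
                     float(adv.value), float(rec.value)]
            n_batches += 1

        means = sums / max(n_batches, 1)
        val_metrics = None
        if len(val_idx):
            val_metrics = _validation_metrics(dsc, X_val, y_val)
        history.append(HistoryRecord(
            epoch=epoch, loss_d=means[0], loss_g=means[1], loss_sup=means[2],
            loss_usup=means[3], loss_cons=means[4], loss_pseudo=means[5],
            loss_adv=means[6], loss_rec=means[7], n_pseudo=n_pseudo_epoch,
            val_metrics=val_metrics,
        ))
    return gen, dsc, history


def predict(dsc: DiscriminatorNet, X: np.ndarray):
    """Classify with the retained discriminator.

    Label = argmax over the two real classes; score is the renormalised
    melanoma probability p_mel / (p_mel + p_non), suitable for AUC.
    """
    probs = dsc.forward(np.asarray(X, dtype=np.float64))
    p_non = probs[:, CLASS_NON_MELANOMA]
    p_mel = probs[:, CLASS_MELANOMA]
    labels = (p_mel > p_non).astype(np.int64)
    scores = p_mel / np.clip(p_mel + p_non, EPS, None)
    return labels, scores


def _validation_metrics(dsc, X_val, y_val):
    from .metrics import MetricsReport, classification_metrics, confusion_from_labels, auc_score

    labeled = y_val != UNLABELED
    if labeled.sum() == 0:
        return None
    y_true = y_val[labeled]
    y_pred, scores = predict(dsc, X_val[labeled])
    import warnings

    with warnings.catch_warnings():
        # single-class predictions early in training are expected, not news
        warnings.simplefilter("ignore", UserWarning)
        report = classification_metrics(confusion_from_labels(y_true, y_pred))
    if len(np.unique(y_true)) == 2:
        report = report.with_auc(auc_score(scores, y_true))
    return report
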