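"""Scikit-learn estimator interface to the semi-supervised GAN classifier.

``SSGANClassifier`` follows the sklearn semi-supervised convention:
``fit(X, y)`` where ``y`` holds class labels 0 (non-melanoma) /
1 (melanoma) and ``-1`` for unlabeled rows.  After fitting, the
generator is discarded for inference and the discriminator classifies
by argmax over the two real-class probabilities.  The estimator is
clonable, works in sklearn pipelines, and exposes the trained networks
and per-epoch history as fitted attributes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .data import FeatureDataset, UNLABELED, oversample_minority
from .losses import LossWeights
from .networks import MLPSpec
from .training import TrainingConfig, predict as _predict, train_ssgan

__all__ = ["SSGANClassifier"]


class SSGANClassifier(ClassifierMixin, BaseEstimator):
    """Semi-supervised GAN melanoma/non-melanoma classifier.

    Parameters mirror the tunable hyperparameters of the method: network
    shape (layers, width, activation, dropout), optimisation (batch size,
    epochs, learning rates, noise size) and the hybrid-loss weights
    (reconstruction λ_r, consistency λ_c, pseudo-label λ_p with
    confidence threshold τ, augmentation σ).  Setting an auxiliary
    weight to zero, or ``use_attention=False``, yields the corresponding
    ablation variant with no code change.
    """

    def __init__(self, *, batch_size=64, epochs=64, lr_g=1e-3, lr_d=1e-3,
                 noise_size=16, n_layers_g=2, n_layers_d=2, hidden_width=64,
                 activation="relu", dropout_rate=0.0, lambda_r=0.42,
                 lambda_consistency=0.28, lambda_pseudo=0.41, tau=0.9,
                 aug_sigma=0.1, use_attention=True, oversample=True,
                 val_fraction=0.2, random_state=0):
        self.batch_size = batch_size
        self.epochs = epochs
        self.lr_g = lr_g
        self.lr_d = lr_d
        self.noise_size = noise_size
        self.n_layers_g = n_layers_g
        self.n_layers_d = n_layers_d
        self.hidden_width = hidden_width
        self.activation = activation
        self.dropout_rate = dropout_rate
        self.lambda_r = lambda_r
        self.lambda_consistency = lambda_consistency
        self.lambda_pseudo = lambda_pseudo
        self.tau = tau
        self.aug_sigma = aug_sigma
        self.use_attention = use_attention
        self.oversample = oversample
        self.val_fraction = val_fraction
        self.random_state = random_state

    # -- config plumbing -------------------------------------------------

    def _training_config(self) -> TrainingConfig:
        mlp = dict(hidden_width=self.hidden_width, activation=self.activation,
                   dropout_rate=self.dropout_rate)
        return TrainingConfig(
            batch_size=self.batch_size,
            epochs=self.epochs,
            lr_g=self.lr_g,
            lr_d=self.lr_d,
            noise_size=self.noise_size,
            g_spec=MLPSpec(n_layers=self.n_layers_g, **mlp),
            d_spec=MLPSpec(n_layers=self.n_layers_d, **mlp),
            weights=LossWeights(
                lambda_r=self.lambda_r,
                lambda_consistency=self.lambda_consistency,
                lambda_pseudo=self.lambda_pseudo,
                tau=self.tau,
            ),
            aug_sigma=self.aug_sigma,
            seed=self.random_state,
            use_attention=self.use_attention,
            val_fraction=self.val_fraction,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        data = FeatureDataset(features=X, labels=y)
        if self.oversample:
            labeled = data.labels != UNLABELED
            counts = np.bincount(data.labels[labeled], minlength=2)
            if counts.min() > 0 and counts[0] != counts[1]:
                data = oversample_minority(data, seed=self.random_state)
        config = self._training_config()
        self.generator_, self.discriminator_, self.history_ = train_ssgan(data, config)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "discriminator_")
        labels, _ = _predict(self.discriminator_, X)
        return labels

    def predict_proba(self, X):
        """Probabilities over the two real classes, renormalised to sum 1."""
        check_is_fitted(self, "discriminator_")
        probs = self.discriminator_.forward(np.asarray(X, dtype=np.float64))
        real = probs[:, :2]
        return real / real.sum(axis=1, keepdims=True)

    def decision_function(self, X):
        """Melanoma score p_mel / (p_mel + p_non), shifted to be 0-centred."""
        check_is_fitted(self, "discriminator_")
        _, scores = _predict(self.discriminator_, X)
        return scores - 0.5

    def melanoma_score(self, X):
        check_is_fitted(self, "discriminator_")
        _, scores = _predict(self.discriminator_, X)
        return scores

    def sample(self, n: int, seed: int = 0):
        """Draw n synthetic feature vectors from the trained generator."""
        check_is_fitted(self, "generator_")
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, self.generator_.noise_size))
        return self.generator_.forward(z)
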