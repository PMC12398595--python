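"""Synthetic feature-vector datasets for semi-supervised melanoma classification.

Real dermoscopy pipelines pass lesion images through a convolutional
feature extractor and classify the resulting feature vectors.  At desk
scale this module emulates those feature distributions with a Gaussian
mixture: two imbalanced classes (melanoma / non-melanoma), several modes
per class standing in for lesion subtypes (differences in shape, colour
gradation and size), additive observation noise, and a partial-label
regime in which only a fraction of the training rows keep their labels.

Also provides the split / oversampling / augmentation utilities the
training protocol relies on: stratified semi-supervised label masking,
stratified k-fold partitions, random oversampling of the minority class
and feature-space Gaussian augmentation for consistency regularisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

UNLABELED = -1

__all__ = [
    "UNLABELED",
    "FeatureDataset",
    "MixtureSpec",
    "ring_mixture_spec",
    "generate_mixture_dataset",
    "make_semisupervised_split",
    "stratified_kfold",
    "oversample_minority",
    "augment_features",
    "read_dataset_tsv",
    "write_dataset_tsv",
]


@dataclass(frozen=True)
class FeatureDataset:
    """An n × d feature matrix with ternary labels.

    Labels: 0 = non-melanoma, 1 = melanoma, -1 = unlabeled.  When labels
    have been masked by :func:`make_semisupervised_split`, the pre-mask
    ground truth is retained in ``true_labels`` for evaluation oracles
    only; training code never reads it.
    """

    features: np.ndarray
    labels: np.ndarray
    split: np.ndarray | None = None
    true_labels: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        X = np.asarray(self.features, dtype=np.float64)
        y = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValueError("features must be a 2-D matrix with d >= 1 columns")
        if y.shape != (X.shape[0],):
            raise ValueError("labels must be a vector with one entry per row")
        if not np.isfinite(X).all():
            raise ValueError("features contain non-finite values")
        if not np.isin(y, (-1, 0, 1)).all():
            raise ValueError("labels must lie in {-1, 0, 1}")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def labeled_mask(self) -> np.ndarray:
        return self.labels != UNLABELED


@dataclass(frozen=True)
class MixtureSpec:
    """Isotropic Gaussian mixture over feature space.

    ``modes`` is a sequence of ``(mean, std, class_label, weight)``
    tuples; weights are normalised to sum to one.  ``noise_std`` adds
    independent observation noise on top of each draw.
    """

    modes: tuple
    d: int
    noise_std: float = 0.0

    def __post_init__(self):
        if self.d < 1:
            raise ValueError("MixtureSpec.d must be >= 1")
        if self.noise_std < 0:
            raise ValueError("MixtureSpec.noise_std must be >= 0")
        if not self.modes:
            raise ValueError("MixtureSpec.modes must be non-empty")
        norm_modes = []
        classes = set()
        for mean, std, cls, weight in self.modes:
            mean = np.asarray(mean, dtype=np.float64)
            if mean.shape != (self.d,):
                raise ValueError(
                    f"MixtureSpec.modes: mean shape {mean.shape} != ({self.d},)"
                )
            if std < 0:
                raise ValueError("MixtureSpec.modes: std must be >= 0")
            if cls not in (0, 1):
                raise ValueError("MixtureSpec.modes: class must be 0 or 1")
            if weight <= 0:
                raise ValueError("MixtureSpec.modes: weight must be > 0")
            classes.add(cls)
            norm_modes.append((mean, float(std), int(cls), float(weight)))
        if classes != {0, 1}:
            raise ValueError("MixtureSpec.modes: need at least one mode per class")
        total = sum(m[3] for m in norm_modes)
        norm_modes = tuple((m, s, c, w / total) for m, s, c, w in norm_modes)
        object.__setattr__(self, "modes", norm_modes)

    @property
    def weights(self) -> np.ndarray:
        return np.array([m[3] for m in self.modes])

    @property
    def means(self) -> np.ndarray:
        return np.stack([m[0] for m in self.modes])

    @property
    def mode_classes(self) -> np.ndarray:
        return np.array([m[2] for m in self.modes])

    def to_dict(self) -> dict:
        return {
            "d": self.d,
            "noise_std": self.noise_std,
            "modes": [
                {"mean": m.tolist(), "std": s, "class": c, "weight": w}
                for m, s, c, w in self.modes
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MixtureSpec":
        modes = tuple(
            (m["mean"], m["std"], m["class"], m["weight"]) for m in payload["modes"]
        )
        return cls(modes=modes, d=int(payload["d"]), noise_std=float(payload["noise_std"]))


def ring_mixture_spec(
    n_modes: int = 8,
    radius: float = 4.0,
    d: int = 16,
    mode_std: float = 0.25,
    noise_std: float = 0.1,
    melanoma_weight: float = 0.3,
) -> MixtureSpec:
    """Default desk-scale fixture: modes on a ring in the first two feature
    dimensions, alternating classes, melanoma the minority class.

    Eight modes (four per class) give enough within-class multimodality
    to exhibit generator mode collapse while staying cheap on one CPU.
    """
    if n_modes < 2 or n_modes % 2:
        raise ValueError("n_modes must be an even integer >= 2")
    modes = []
    for i in range(n_modes):
        angle = 2.0 * np.pi * i / n_modes
        mean = np.zeros(d)
        mean[0] = radius * np.cos(angle)
        mean[1] = radius * np.sin(angle)
        cls = i % 2
        class_total = melanoma_weight if cls == 1 else 1.0 - melanoma_weight
        modes.append((mean, mode_std, cls, class_total / (n_modes / 2)))
    return MixtureSpec(modes=tuple(modes), d=d, noise_std=noise_std)


def generate_mixture_dataset(spec: MixtureSpec, n: int, seed: int) -> FeatureDataset:
    """Draw ``n`` rows from the mixture; label = class of the drawn mode."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    assignment = rng.choice(len(spec.modes), size=n, p=spec.weights)
    X = np.empty((n, spec.d))
    y = np.empty(n, dtype=np.int64)
    for i, k in enumerate(assignment):
        mean, std, cls, _ = spec.modes[k]
        X[i] = mean + std * rng.standard_normal(spec.d)
        y[i] = cls
    if spec.noise_std > 0:
        X += spec.noise_std * rng.standard_normal((n, spec.d))
    return FeatureDataset(features=X, labels=y)


def make_semisupervised_split(
    data: FeatureDataset, labeled_fraction: float, seed: int
) -> FeatureDataset:
    """Mask labels so that round(labeled_fraction * n) stratified rows keep
    theirs; the remainder become -1.  Ground truth moves to ``true_labels``.

    Per-class quotas are floor(fraction * n_class) with the leftover slots
    going to the largest fractional remainders, so the total matches the
    rounded target deterministically.
    """
    if not (0.0 < labeled_fraction <= 1.0):
        raise ValueError("labeled_fraction must lie in (0, 1]")
    if data.n == 0:
        raise ValueError("cannot split an empty dataset")
    if (data.labels == UNLABELED).any():
        raise ValueError("dataset already contains unlabeled rows")
    rng = np.random.default_rng(seed)
    n_target = int(round(labeled_fraction * data.n))
    classes, counts = np.unique(data.labels, return_counts=True)
    raw = labeled_fraction * counts
    quotas = np.floor(raw).astype(int)
    remainder = n_target - quotas.sum()
    if remainder > 0:
        order = np.argsort(-(raw - quotas), kind="stable")
        quotas[order[:remainder]] += 1
    quotas = np.minimum(quotas, counts)
    keep = np.zeros(data.n, dtype=bool)
    for cls, quota in zip(classes, quotas):
        idx = np.flatnonzero(data.labels == cls)
        keep[rng.choice(idx, size=quota, replace=False)] = True
    masked = np.where(keep, data.labels, UNLABELED)
    return replace(data, labels=masked, true_labels=data.labels.copy())


def stratified_kfold(data: FeatureDataset, k: int, seed: int):
    """Stratified k-fold index partitions over the labeled rows.

    Thin wrapper over sklearn's StratifiedKFold (shuffled, seeded); folds
    preserve class prevalence to within one sample.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = data.labels
    if (y == UNLABELED).any():
        raise ValueError("stratified_kfold expects fully labeled data")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs >= k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(train, test) for train, test in skf.split(data.features, y)]


def oversample_minority(data: FeatureDataset, seed: int) -> FeatureDataset:
    """Random oversampling: duplicate minority-class labeled rows (with
    replacement) until labeled class counts are equal.  Unlabeled rows
    pass through untouched."""
    rng = np.random.default_rng(seed)
    labeled = data.labeled_mask()
    y_lab = data.labels[labeled]
    classes, counts = np.unique(y_lab, return_counts=True)
    if len(classes) < 2:
        raise ValueError("oversample_minority needs both classes among labeled rows")
    if counts[0] == counts[1]:
        return data
    minority = classes[np.argmin(counts)]
    deficit = int(counts.max() - counts.min())
    pool = np.flatnonzero(labeled & (data.labels == minority))
    extra = rng.choice(pool, size=deficit, replace=True)
    X = np.vstack([data.features, data.features[extra]])
    y = np.concatenate([data.labels, data.labels[extra]])
    split = None
    if data.split is not None:
        split = np.concatenate([data.split, data.split[extra]])
    true = None
    if data.true_labels is not None:
        true = np.concatenate([data.true_labels, data.true_labels[extra]])
    return FeatureDataset(features=X, labels=y, split=split, true_labels=true)


def augment_features(X: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Feature-space augmentation: add elementwise N(0, sigma²) noise.

    The image-space flips/rotations of the original pipeline have no
    meaning on feature vectors; additive Gaussian noise is the admissible
    transformation used for consistency regularisation here.
    """
    X = np.asarray(X, dtype=np.float64)
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return X.copy()
    rng = np.random.default_rng(seed)
    return X + sigma * rng.standard_normal(X.shape)


# -- TSV persistence -----------------------------------------------------


def write_dataset_tsv(data: FeatureDataset, path) -> None:
    """Write ``f1..fd<TAB>label`` rows; 9 significant digits."""
    df = pd.DataFrame(
        data.features, columns=[f"f{i + 1}" for i in range(data.d)]
    )
    df["label"] = data.labels
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_dataset_tsv(path) -> FeatureDataset:
    df = pd.read_csv(path, sep="\t")
    if "label" not in df.columns:
        raise ValueError("dataset file is missing the 'label' column")
    y = df.pop("label").to_numpy(dtype=np.int64)
    return FeatureDataset(features=df.to_numpy(dtype=np.float64), labels=y)
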