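"""Classification metrics, the receptive-field recursion, and
distribution metrics for generator quality.

Classification metrics follow the usual confusion-matrix definitions
(accuracy, precision, recall/TPR, specificity, F-measure, G-means,
FNR = 1 − TPR) with melanoma the positive class.  Generator quality is
summarised by four two-sample statistics: unbiased RBF-kernel maximum
mean discrepancy (median-heuristic bandwidth), a k-NN estimator of
KL(real ‖ fake), sliced Wasserstein-1 distance (random unit
projections, exact one-dimensional transport per slice) and a Mode
Score computed from an oracle class-posterior over mixture modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import wasserstein_distance
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "LayerStack",
    "GanMetricsReport",
    "VGG16_STACK",
    "confusion_from_labels",
    "classification_metrics",
    "auc_score",
    "receptive_field",
    "mmd_rbf",
    "kl_divergence_knn",
    "sliced_wasserstein",
    "mode_score",
    "nearest_mode_posterior",
    "distribution_metrics",
    "relative_change",
]

_EPS = 1e-12


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_from_labels(y_true, y_pred) -> ConfusionCounts:
    """Counts with melanoma (label 1) as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


@dataclass(frozen=True)
class MetricsReport:
    """Fractional classification metrics; multiply by 100 for percent.

    ``degenerate`` lists any ratios whose denominator was zero (those
    are reported as 0).
    """

    accuracy: float
    precision: float
    recall_tpr: float
    specificity: float
    f_measure: float
    g_means: float
    fnr: float
    auc: float | None = None
    degenerate: tuple = ()

    def with_auc(self, auc: float) -> "MetricsReport":
        return _dc_replace(self, auc=float(auc))

    def as_percent(self) -> dict:
        out = {
            "accuracy": 100 * self.accuracy,
            "precision": 100 * self.precision,
            "recall_tpr": 100 * self.recall_tpr,
            "specificity": 100 * self.specificity,
            "f_measure": 100 * self.f_measure,
            "g_means": 100 * self.g_means,
            "fnr": 100 * self.fnr,
        }
        if self.auc is not None:
            out["auc"] = self.auc  # AUC stays a fraction
        return out


def _ratio(num: float, den: float, name: str, degenerate: list) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def classification_metrics(c: ConfusionCounts) -> MetricsReport:
    """Confusion-matrix metrics; zero-denominator ratios become 0 and are
    flagged in ``degenerate`` (with a warning)."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    degenerate: list = []
    accuracy = (c.TP + c.TN) / c.total
    precision = _ratio(c.TP, c.TP + c.FP, "precision", degenerate)
    recall = _ratio(c.TP, c.TP + c.FN, "recall", degenerate)
    specificity = _ratio(c.TN, c.TN + c.FP, "specificity", degenerate)
    f_measure = _ratio(2 * precision * recall, precision + recall, "f_measure", degenerate)
    g_means = float(np.sqrt(recall * specificity))
    if degenerate:
        warnings.warn(
            f"zero-denominator metrics reported as 0: {degenerate}", stacklevel=2
        )
    return MetricsReport(
        accuracy=accuracy, precision=precision, recall_tpr=recall,
        specificity=specificity, f_measure=f_measure, g_means=g_means,
        fnr=1.0 - recall, degenerate=tuple(degenerate),
    )


def auc_score(scores, labels) -> float:
    """Rank-based (Mann–Whitney) AUC; ties share 0.5."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


# -- receptive field -----------------------------------------------------


@dataclass(frozen=True)
class LayerStack:
    """Ordered (kernel, stride) pairs of a convolution/pooling stack."""

    layers: tuple

    def __post_init__(self):
        if not self.layers:
            raise ValueError("LayerStack must be non-empty")
        layers = tuple((int(k), int(s)) for k, s in self.layers)
        for k, s in layers:
            if k < 1 or s < 1:
                raise ValueError("kernel and stride must be >= 1")
        object.__setattr__(self, "layers", layers)


def _vgg16_layers():
    layers = []
    for n_convs in (2, 2, 3, 3, 3):
        layers += [(3, 1)] * n_convs + [(2, 2)]
    return tuple(layers)


#: The canonical VGG-16 feature stack: 13 convolutions (k=3, s=1) and
#: 5 max-pools (k=2, s=2) in the standard 2-2-3-3-3 block order.
VGG16_STACK = LayerStack(_vgg16_layers())


def receptive_field(stack: LayerStack) -> int:
    """R_1 = k_1; R_l = R_{l-1} + (k_l − 1)·Π_{i<l} s_i."""
    r = 0
    jump = 1
    for index, (k, s) in enumerate(stack.layers):
        if index == 0:
            r = k
        else:
            r += (k - 1) * jump
        jump *= s
    return int(r)


# -- distribution metrics ------------------------------------------------


def _median_bandwidth(X: np.ndarray, Y: np.ndarray) -> float:
    Z = np.vstack([X, Y])
    dists = cdist(Z, Z)
    med = np.median(dists[np.triu_indices_from(dists, k=1)])
    return float(med) if med > 0 else 1.0


def mmd_rbf(X: np.ndarray, Y: np.ndarray, bandwidth: float | None = None) -> float:
    """Unbiased RBF-kernel MMD² statistic, clipped at 0.

    The unbiased estimator can dip slightly negative for identical
    samples; the report convention is non-negative.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    n, m = len(X), len(Y)
    if n < 2 or m < 2:
        raise ValueError("MMD needs at least 2 samples per side")
    if bandwidth is None:
        bandwidth = _median_bandwidth(X, Y)
    gamma = 1.0 / (2.0 * bandwidth**2)
    Kxx = np.exp(-gamma * cdist(X, X, "sqeuclidean"))
    Kyy = np.exp(-gamma * cdist(Y, Y, "sqeuclidean"))
    Kxy = np.exp(-gamma * cdist(X, Y, "sqeuclidean"))
    np.fill_diagonal(Kxx, 0.0)
    np.fill_diagonal(Kyy, 0.0)
    stat = (
        Kxx.sum() / (n * (n - 1))
        + Kyy.sum() / (m * (m - 1))
        - 2.0 * Kxy.mean()
    )
    return float(max(stat, 0.0))


def kl_divergence_knn(X: np.ndarray, Y: np.ndarray, k: int = 5) -> float:
    """k-NN differential-entropy estimate of KL(P_X ‖ P_Y), clipped at 0.

    Wang–Kulkarni–Verdú estimator: for each x, compare the distance to
    its k-th neighbour within X against the k-th neighbour in Y.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    n, m = len(X), len(Y)
    d = X.shape[1]
    if n <= k or m < k:
        raise ValueError(f"KL estimator needs more than k={k} samples per side")
    nn_x = NearestNeighbors(n_neighbors=k + 1).fit(X)
    r_k = nn_x.kneighbors(X)[0][:, k]
    nn_y = NearestNeighbors(n_neighbors=k).fit(Y)
    s_k = nn_y.kneighbors(X)[0][:, k - 1]
    r_k = np.maximum(r_k, _EPS)
    s_k = np.maximum(s_k, _EPS)
    est = d * np.mean(np.log(s_k / r_k)) + np.log(m / (n - 1.0))
    return float(max(est, 0.0))


def sliced_wasserstein(X: np.ndarray, Y: np.ndarray, n_slices: int = 64,
                       seed: int = 0) -> float:
    """Sliced W₁: mean exact 1-D transport cost over random unit projections."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape[1] != Y.shape[1]:
        raise ValueError("dimension mismatch between samples")
    d = X.shape[1]
    if d == 1:
        return float(wasserstein_distance(X[:, 0], Y[:, 0]))
    rng = np.random.default_rng(seed)
    total = 0.0
    for _ in range(n_slices):
        u = rng.standard_normal(d)
        u /= np.linalg.norm(u)
        total += wasserstein_distance(X @ u, Y @ u)
    return float(total / n_slices)


def nearest_mode_posterior(spec):
    """Hard nearest-mode assignment oracle for a known MixtureSpec.

    Returns a callable X → one-hot posterior over the mixture modes; used
    as the Mode Score classifier on synthetic fixtures, where the data
    generating process is known and no trained model is required.
    """
    means = spec.means

    def posterior(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        assign = np.argmin(cdist(X, means), axis=1)
        out = np.zeros((len(X), len(means)))
        out[np.arange(len(X)), assign] = 1.0
        return out

    return posterior


def _kl_discrete(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS, 1.0)
    q = np.clip(q, _EPS, 1.0)
    return np.sum(p * np.log(p / q), axis=-1)


def mode_score(real_X: np.ndarray, fake_X: np.ndarray, posterior) -> float:
    """exp( E_fake KL(p(y|x) ‖ p_real(y)) − KL(p_fake(y) ‖ p_real(y)) ).

    High when generated samples are confidently assigned to modes *and*
    their mode marginal matches the real data's; collapse onto few modes
    inflates the second term and drives the score toward 1 or below.
    """
    p_fake = posterior(fake_X)
    p_real_marg = posterior(real_X).mean(axis=0)
    p_fake_marg = p_fake.mean(axis=0)
    term1 = float(np.mean(_kl_discrete(p_fake, p_real_marg[None, :])))
    term2 = float(_kl_discrete(p_fake_marg[None, :], p_real_marg[None, :])[0])
    return float(np.exp(term1 - term2))


@dataclass(frozen=True)
class GanMetricsReport:
    mmd: float
    kld: float
    wd: float
    mode_score: float | None = None


def distribution_metrics(real_X, fake_X, mode_assign=None, n_slices: int = 64,
                         k: int = 5, seed: int = 0,
                         want_mode_score: bool = None) -> GanMetricsReport:
    """MMD, KL and sliced-W₁ between real and generated samples, plus the
    Mode Score when an oracle posterior is supplied."""
    real_X = np.asarray(real_X, dtype=np.float64)
    fake_X = np.asarray(fake_X, dtype=np.float64)
    if real_X.size == 0 or fake_X.size == 0:
        raise ValueError("both samples must be non-empty")
    if real_X.shape[1] != fake_X.shape[1]:
        raise ValueError(
            f"dimension mismatch: {real_X.shape[1]} vs {fake_X.shape[1]}"
        )
    if want_mode_score and mode_assign is None:
        raise ValueError("Mode Score requested without a mode_assign oracle")
    ms = mode_score(real_X, fake_X, mode_assign) if mode_assign is not None else None
    return GanMetricsReport(
        mmd=mmd_rbf(real_X, fake_X),
        kld=kl_divergence_knn(real_X, fake_X, k=k),
        wd=sliced_wasserstein(real_X, fake_X, n_slices=n_slices, seed=seed),
        mode_score=ms,
    )


def relative_change(before: float, after: float, mode: str = "relative") -> float:
    """Percent change between two summary numbers (sign preserved)."""
    if mode not in ("relative", "absolute"):
        raise ValueError("mode must be 'relative' or 'absolute'")
    if mode == "relative":
        if before == 0:
            raise ValueError("relative change undefined for before == 0")
        return float(100.0 * (after - before) / before)
    return float(after - before)
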