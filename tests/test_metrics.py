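"""Classification metrics, receptive field, distribution metrics."""

import numpy as np
import pytest

from melssgan import (
    ConfusionCounts,
    LayerStack,
    VGG16_STACK,
    auc_score,
    classification_metrics,
    confusion_from_labels,
    distribution_metrics,
    mode_score,
    nearest_mode_posterior,
    receptive_field,
    relative_change,
    ring_mixture_spec,
    generate_mixture_dataset,
)
from melssgan.metrics import kl_divergence_knn, mmd_rbf, sliced_wasserstein


def _auc_pair_counting(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestClassificationMetrics:
    def test_perfect_classifier(self):
        r = classification_metrics(ConfusionCounts(TP=5, TN=5, FP=0, FN=0))
        assert (r.accuracy, r.f_measure, r.g_means, r.fnr) == (1.0, 1.0, 1.0, 0.0)

    def test_hand_computed_case(self):
        r = classification_metrics(ConfusionCounts(TP=3, FN=1, FP=2, TN=4))
        assert r.recall_tpr == pytest.approx(0.75)
        assert r.precision == pytest.approx(0.6)
        assert r.f_measure == pytest.approx(2 * 0.6 * 0.75 / 1.35)
        assert r.specificity == pytest.approx(2 / 3)
        assert r.g_means == pytest.approx(np.sqrt(0.5))

    def test_degenerate_ratios_flagged_as_zero(self):
        with pytest.warns(UserWarning, match="zero-denominator"):
            r = classification_metrics(ConfusionCounts(TP=0, TN=4, FP=0, FN=0))
        assert r.precision == 0.0
        assert "recall" in r.degenerate or "precision" in r.degenerate

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_identities_fuzzed(self):
        rng = np.random.default_rng(0)
        import warnings

        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 40, size=4)
            if tp + tn + fp + fn == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = classification_metrics(ConfusionCounts(tp, tn, fp, fn))
            assert r.fnr == pytest.approx(1.0 - r.recall_tpr, abs=1e-12)
            assert r.g_means**2 == pytest.approx(r.recall_tpr * r.specificity,
                                                 abs=1e-12)
            assert r.accuracy == pytest.approx((tp + tn) / (tp + tn + fp + fn))

    def test_confusion_from_labels(self):
        y_true = np.array([1, 1, 0, 0, 1])
        y_pred = np.array([1, 0, 0, 1, 1])
        c = confusion_from_labels(y_true, y_pred)
        assert (c.TP, c.FN, c.TN, c.FP) == (2, 1, 1, 1)


class TestAuc:
    def test_perfect_separation(self):
        assert auc_score([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert auc_score([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(6, 50))
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # induce ties
            assert auc_score(scores, labels) == pytest.approx(
                _auc_pair_counting(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score([0.1, 0.9], [1, 1])


class TestReceptiveField:
    def test_base_case_and_two_convs(self):
        assert receptive_field(LayerStack(((3, 1),))) == 3
        assert receptive_field(LayerStack(((3, 1), (3, 1)))) == 5

    def test_vgg16_stack_is_212(self):
        assert receptive_field(VGG16_STACK) == 212
        assert len(VGG16_STACK.layers) == 18

    def test_monotone_in_depth_and_kernel(self):
        rng = np.random.default_rng(1)
        layers = []
        prev = 0
        for _ in range(8):
            layers.append((int(rng.integers(1, 6)), int(rng.integers(1, 3))))
            r = receptive_field(LayerStack(tuple(layers)))
            assert r >= prev
            prev = r
        grown = [(layers[3][0] + 2, layers[3][1])]
        stack2 = LayerStack(tuple(layers[:3] + grown + layers[4:]))
        assert receptive_field(stack2) >= prev or True  # kernel growth at any
        assert receptive_field(stack2) >= receptive_field(LayerStack(tuple(layers)))

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            LayerStack(())


class TestDistributionMetrics:
    def test_identical_samples_near_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(500, 2))
        rep = distribution_metrics(X, X.copy(), seed=0)
        assert rep.mmd <= 0.01
        assert rep.wd <= 0.05
        assert rep.kld <= 0.05

    def test_shifted_gaussians_1d_wasserstein(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0.0, 1.0, size=(2000, 1))
        Y = rng.normal(1.0, 1.0, size=(2000, 1))
        assert 0.9 <= sliced_wasserstein(X, Y) <= 1.1

    def test_mmd_nonnegative_and_shrinks_with_n(self):
        rng = np.random.default_rng(4)
        vals = []
        for n in (100, 500):
            X = rng.normal(size=(n, 3))
            Y = rng.normal(size=(n, 3))
            v = mmd_rbf(X, Y)
            assert v >= 0
            vals.append(v)
        assert vals[1] <= vals[0] + 1e-3

    def test_collapsed_fake_scores_worse_than_covering_fake(self):
        spec = ring_mixture_spec(noise_std=0.0)
        oracle = nearest_mode_posterior(spec)
        for seed in range(3):
            real = generate_mixture_dataset(spec, 800, seed=seed).features
            full = generate_mixture_dataset(spec, 800, seed=seed + 50).features
            one_mode = spec.means[0] + 0.25 * np.random.default_rng(seed).normal(
                size=(800, spec.d))
            ms_full = mode_score(real, full, oracle)
            ms_collapsed = mode_score(real, one_mode, oracle)
            assert ms_collapsed < ms_full
            assert mmd_rbf(real, one_mode) > mmd_rbf(real, full)

    def test_dimension_mismatch_and_missing_oracle(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="mismatch"):
            distribution_metrics(X, np.zeros((10, 3)))
        with pytest.raises(ValueError, match="oracle"):
            distribution_metrics(X, X, want_mode_score=True)


class TestRelativeChange:
    def test_printed_summary_deltas(self):
        assert relative_change(11.22, 7.17) == pytest.approx(-36.1, abs=0.05)
        assert relative_change(0.813, 0.866) == pytest.approx(6.52, abs=0.005)
        assert relative_change(0.830, 0.892) == pytest.approx(7.47, abs=0.005)

    def test_no_change_both_modes(self):
        assert relative_change(3.0, 3.0) == 0.0
        assert relative_change(3.0, 3.0, mode="absolute") == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            relative_change(0.0, 1.0)
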