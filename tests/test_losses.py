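"""All eight loss terms against independent scalar-loop oracles."""

import math

import numpy as np
import pytest

from melssgan import (
    LossWeights,
    consistency_loss,
    d_supervised_loss,
    d_total_loss,
    d_unsupervised_loss,
    g_adversarial_loss,
    g_total_loss,
    pseudo_label_loss,
    reconstruction_loss,
)
from melssgan.losses import EPS

FAKE = 2


# -- scalar-loop oracles (kept deliberately naive) -----------------------


def _oracle_sup(probs, labels):
    total = 0.0
    for row, y in zip(probs, labels):
        total += -math.log(min(max(row[y], EPS), 1 - EPS))
    return total / len(labels)


def _oracle_usup(pr, pf):
    a = sum(-math.log(min(max(1 - row[FAKE], EPS), 1 - EPS)) for row in pr)
    b = sum(-math.log(min(max(row[FAKE], EPS), 1 - EPS)) for row in pf)
    out = 0.0
    if len(pr):
        out += a / len(pr)
    if len(pf):
        out += b / len(pf)
    return out


def _oracle_adv(pf):
    return sum(-math.log(min(max(1 - row[FAKE], EPS), 1 - EPS)) for row in pf) / len(pf)


def _oracle_rec(x, xr):
    return sum(
        math.sqrt(sum((a - b) ** 2 for a, b in zip(r1, r2)))
        for r1, r2 in zip(x, xr)
    ) / len(x)


def _oracle_cons(p, pa):
    return sum(
        sum((a - b) ** 2 for a, b in zip(r1, r2)) for r1, r2 in zip(p, pa)
    ) / len(p)


def _oracle_pseudo(probs, tau):
    losses = []
    for row in probs:
        conf = max(row[0], row[1])
        if conf >= tau:
            losses.append(-math.log(min(max(conf, EPS), 1 - EPS)))
    if not losses:
        return 0.0, 0
    return sum(losses) / len(losses), len(losses)


class TestSupervised:
    def test_perfect_prediction_is_zero(self):
        probs = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        assert d_supervised_loss(probs, np.array([0, 1])) < 1e-6

    def test_analytic_half(self):
        probs = np.array([[0.5, 0.25, 0.25]])
        assert d_supervised_loss(probs, np.array([0])) == pytest.approx(math.log(2))

    def test_matches_oracle(self, prob_rows):
        labels = np.array([0, 1, 1, 0, 1])
        assert d_supervised_loss(prob_rows, labels) == pytest.approx(
            _oracle_sup(prob_rows, labels), abs=1e-8
        )

    def test_unlabeled_rejected(self, prob_rows):
        with pytest.raises(ValueError, match="labeled-only"):
            d_supervised_loss(prob_rows, np.array([0, 1, -1, 0, 1]))


class TestUnsupervisedAndAdversarial:
    def test_perfect_discrimination_is_zero(self):
        real = np.array([[0.6, 0.4, 0.0]])
        fake = np.array([[0.0, 0.0, 1.0]])
        assert d_unsupervised_loss(real, fake) < 1e-5

    def test_analytic_half_half(self):
        row = np.array([[0.25, 0.25, 0.5]])
        assert d_unsupervised_loss(row, row) == pytest.approx(2 * math.log(2), rel=1e-6)

    def test_matches_oracle(self, prob_rows):
        assert d_unsupervised_loss(prob_rows[:3], prob_rows[3:]) == pytest.approx(
            _oracle_usup(prob_rows[:3], prob_rows[3:]), abs=1e-8
        )

    def test_empty_both_rejected(self):
        empty = np.empty((0, 3))
        with pytest.raises(ValueError):
            d_unsupervised_loss(empty, empty)

    def test_generator_wins_gives_zero(self):
        fake = np.array([[0.7, 0.3, 0.0]])
        assert g_adversarial_loss(fake) < 1e-6

    def test_adversarial_analytic_and_oracle(self, prob_rows):
        assert g_adversarial_loss(np.array([[0.25, 0.25, 0.5]])) == pytest.approx(
            math.log(2), rel=1e-6
        )
        assert g_adversarial_loss(prob_rows) == pytest.approx(
            _oracle_adv(prob_rows), abs=1e-8
        )


class TestReconstruction:
    def test_identity_is_zero(self):
        x = np.ones((3, 4))
        assert reconstruction_loss(x, x) == 0.0

    def test_three_four_five(self):
        x = np.array([[0.0, 0.0]])
        xr = np.array([[3.0, 4.0]])
        assert reconstruction_loss(x, xr) == pytest.approx(5.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(8)
        x, xr = rng.normal(size=(5, 6)), rng.normal(size=(5, 6))
        assert reconstruction_loss(x, xr) == pytest.approx(
            _oracle_rec(x, xr), abs=1e-8
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((2, 3)), np.zeros((3, 2)))


class TestTotals:
    def test_generator_total_with_tuned_weight(self):
        # λ = 0.42 is the optimized reconstruction weight (ISIC-2020)
        w = LossWeights(lambda_r=0.42)
        assert g_total_loss(1.0, 2.0, w) == pytest.approx(1.84)

    def test_generator_ablation_switch(self):
        w = LossWeights(lambda_r=0.0)
        assert g_total_loss(1.7, 99.0, w) == 1.7

    @pytest.mark.parametrize("lam", [0.0, 0.3, 1.0])
    def test_generator_total_affine_in_rec(self, lam):
        w = LossWeights(lambda_r=lam)
        assert g_total_loss(2.0, 5.0, w) - g_total_loss(2.0, 1.0, w) == pytest.approx(
            4.0 * lam
        )

    def test_discriminator_total_with_tuned_weights(self):
        # λ_consistency = 0.28, λ_pseudo = 0.41 (ISIC-2020 best values)
        w = LossWeights(lambda_consistency=0.28, lambda_pseudo=0.41)
        assert d_total_loss(1.0, 1.0, 2.0, 3.0, w) == pytest.approx(2.0 + 0.56 + 1.23)

    def test_discriminator_total_vanilla_ablation(self):
        w = LossWeights(lambda_consistency=0.0, lambda_pseudo=0.0)
        assert d_total_loss(0.8, 1.1, 7.0, 9.0, w) == pytest.approx(1.9)

    @pytest.mark.parametrize("field", ["sup", "usup", "cons", "pseudo"])
    def test_discriminator_total_affine_in_each_term(self, field):
        w = LossWeights(lambda_consistency=0.5, lambda_pseudo=0.25)
        base = dict(sup=1.0, usup=1.0, cons=1.0, pseudo=1.0)
        deltas = []
        for v in (0.0, 1.0, 2.0):
            args = dict(base, **{field: v})
            deltas.append(d_total_loss(args["sup"], args["usup"], args["cons"],
                                       args["pseudo"], w))
        assert deltas[2] - deltas[1] == pytest.approx(deltas[1] - deltas[0])


class TestConsistency:
    def test_identical_inputs_zero(self, prob_rows):
        assert consistency_loss(prob_rows, prob_rows) == 0.0

    def test_orthogonal_corners(self):
        a = np.array([[1.0, 0.0, 0.0]])
        b = np.array([[0.0, 1.0, 0.0]])
        assert consistency_loss(a, b) == pytest.approx(2.0)

    def test_matches_oracle(self, prob_rows):
        other = prob_rows[::-1].copy()
        assert consistency_loss(prob_rows, other) == pytest.approx(
            _oracle_cons(prob_rows, other), abs=1e-8
        )


class TestPseudoLabel:
    def test_unreachable_threshold_selects_nothing(self, prob_rows):
        loss, n = pseudo_label_loss(prob_rows, 1.0)
        assert (loss, n) == (0.0, 0)

    def test_single_confident_row(self):
        probs = np.array([[0.95, 0.03, 0.02]])
        loss, n = pseudo_label_loss(probs, 0.9)
        assert n == 1
        assert loss == pytest.approx(-math.log(0.95))

    def test_matches_filter_oracle(self, prob_rows):
        loss, n = pseudo_label_loss(prob_rows, 0.4)
        exp_loss, exp_n = _oracle_pseudo(prob_rows, 0.4)
        assert n == exp_n
        assert loss == pytest.approx(exp_loss, abs=1e-8)

    @pytest.mark.parametrize("tau", [0.0, -0.5, 1.1])
    def test_invalid_tau(self, prob_rows, tau):
        with pytest.raises(ValueError):
            pseudo_label_loss(prob_rows, tau)


def test_all_losses_non_negative_on_random_batches():
    rng = np.random.default_rng(99)
    for _ in range(20):
        raw = rng.random((5, 3)) + 1e-3
        probs = raw / raw.sum(axis=1, keepdims=True)
        labels = rng.integers(0, 2, size=5)
        assert d_supervised_loss(probs, labels) >= 0
        assert d_unsupervised_loss(probs, probs) >= 0
        assert g_adversarial_loss(probs) >= 0
        assert consistency_loss(probs, probs[::-1].copy()) >= 0
        assert pseudo_label_loss(probs, 0.5)[0] >= 0
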