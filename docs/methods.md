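# Methods

## Problem and model

`melssgan` implements a semi-supervised GAN (SS-GAN) for binary melanoma
/ non-melanoma classification over feature vectors, together with the
mutual-learning artificial bee colony (ML-ABC) hyperparameter search
that tunes it.  In a production dermoscopy pipeline the feature vectors
would come from a convolutional extractor (a VGG-16 backbone whose final
convolutional layer has a 212-pixel receptive field, nearly covering a
224 × 224 input); this package works at desk scale on synthetic feature
data with the same statistical structure and exposes the extractor only
as an interface.

The discriminator classifies every input into c + 1 = 3 classes — the
two real classes plus a "fake" class for generated samples — so it can
learn from labeled rows (supervised term), unlabeled rows and generated
rows (unsupervised terms) at once.  Column order is 0 = non-melanoma,
1 = melanoma, 2 = fake.  Its objective is

    L_D = L_sup + L_usup + λ_c·L_consistency + λ_p·L_pseudo

and the generator's is

    L_G = −E_fake log(1 − p_fake) + λ_r·E_x ‖G(D_F(x)) − x‖₂ ,

where `D_F` is the discriminator without its final layer.  The four
auxiliary mechanisms, each removable by a single configuration switch:

- **Reconstruction** (λ_r): the generator must reconstruct real samples
  from their discriminator features, anchoring the fake distribution to
  the real one and countering mode collapse.
- **Self-attention**: both networks prepend a single-head scaled
  dot-product attention block over the minibatch (n tokens of dimension
  d), as a residual with d_k = d, so zeroed attention weights reduce the
  block to the identity — an exact ablation switch.
- **Consistency regularisation** (λ_c): squared distance between the
  class-probability vectors of a sample and a Gaussian-noise augmented
  copy (σ = `aug_sigma`, default 0.1).  Image-space flips/rotations have
  no meaning on feature vectors; additive noise is the admissible
  feature-space transformation.
- **Confidence-based pseudo-labels** (λ_p, τ): unlabeled rows whose best
  *real-class* probability reaches τ are trained on their predicted
  label.  A "fake" pseudo-label for a real image would be meaningless,
  so the argmax is restricted to the two real classes.

Two further protocol rules: unlabeled real rows enter the first
unsupervised term only while the model currently classifies them as
fake (the indicator is recomputed from live predictions each step and
carries no gradient), and after training the generator is discarded —
classification is the argmax over the two real-class probabilities of
the retained discriminator.

## Architecture and numerical choices

Networks are attention-prefixed MLPs.  Hidden layers share one
configurable width (default 64; layer count is the tunable the search
space exposes).  The published objective composes G(D_F(x)) but never
reconciles D_F's width with the generator's input size; here the
discriminator ends in a linear projection to exactly `noise_size` units
before the 3-logit head, which is the single architectural addition
needed to make that composition well-typed.

- Probabilities are clamped to [1e−7, 1 − 1e−7] before logarithms (the
  cross-entropy terms are undefined at 0/1).
- Weight init is uniform scaled by 1/√fan_in, seed-controlled; the
  optimizer is Adam (β₁ = 0.9, β₂ = 0.999) with separate generator /
  discriminator learning rates (default 1e−3 at desk scale).
- One discriminator step then one generator step per minibatch; no early
  stopping (a fixed epoch budget, as in the tuned configurations).
- Training runs on a small reverse-mode autodiff engine over numpy
  (`_autodiff.py`): dense matmuls, broadcasting arithmetic, row-softmax
  and the loss reductions, with gradients checked against central
  differences in the test suite.
- Default loss weights are the tuned ISIC-2020 values λ_r = 0.42,
  λ_c = 0.28, λ_p = 0.41; τ defaults to 0.9 (no tuned value is
  published for τ; 0.9 is the conventional confident-pseudo-label
  threshold).
- `TrainingConfig` enforces the published search ranges (batch 16–512,
  epochs 64–1024, layers 1–10, noise size 16–1024, rates in (0,1)), so
  the smallest legal epoch budget is 64 — the value the desk-scale test
  runs use.

## Synthetic data generator

Real dermoscopy features are imbalanced, multi-modal (many lesion
subtypes per class) and only partially labeled.  The generator emulates
exactly that: an isotropic Gaussian mixture, by default 8 modes (4 per
class, alternating) on a ring of radius 4 in the first two of d = 16
dimensions, mode σ = 0.25, additive observation noise σ = 0.1, melanoma
a 30 % minority, and a stratified 30 % labeled / 70 % unlabeled split.
Ground-truth labels of masked rows move to a shadow field read only by
evaluation code.  Per-class labeled quotas are floor(fraction·n_class)
with leftovers assigned by largest fractional remainder, which makes the
total match round(fraction·n) deterministically.

What this emulates well: class imbalance, within-class multimodality,
partial labels, observation noise.  What it does not: the heavy-tailed,
highly anisotropic geometry of real CNN features, label noise, and
domain shift between acquisition sites.  Passing tests therefore
demonstrate correctness of the method's mechanics and its directional
properties on controlled data, not clinical performance.

## Random-key encoding and ML-ABC

Hyperparameters are encoded in a genome on [0,1]^D: one gene per
continuous/integer parameter (affine map onto [lo, hi]; integers round
half-up), |options| genes per categorical parameter with argmax
selection.  Argmax is permutation-sensitive and invariant under strictly
increasing transforms, so order-preserving colony updates preserve the
decoded choice, and decoding is total over the unit cube.  The published
description of the categorical rule is internally inconsistent (its
ascending-sort illustration would always select the first option); the
argmax rule is the standard random-key-for-selection variant and is the
one implemented.  The preset search spaces nudge two degenerate bounds
(learning rate low end 1e−5, dropout high end 0.95) so every genome
decodes to a trainable configuration.

ML-ABC replaces the classic employed/onlooker move with a directed one:
compare the current source i with a random neighbour k and move the
*worse* position toward the *better* one in one randomly chosen
dimension, with step φ ~ U(0, F) (F defaults to 1; larger F degrades
the exploration/exploitation balance).  The per-dimension update
matters: a full-vector version of the same rule is pure interpolation,
contracts the colony prematurely and stalls around objective ~1 on the
10-D sphere, while the per-dimension rule reaches ~1e−9 in the same
budget and beats classic ABC on sphere and Rastrigin alike (the
package's benchmark tests measure exactly this).  `mutual_candidate`
exposes both forms (`dim=None` moves every coordinate).  Scouts
reinitialise any source whose trial counter reaches `limit` by uniform
redraw.  Onlooker selection uses the classic positivity transform
1/(1+f) (f ≥ 0), 1+|f| (f < 0) applied to the negated maximised
fitness.  For model tuning the fitness is the validation F-measure of a
short-budget training run, seed-fixed per evaluation.

## Metrics

Classification: accuracy, precision, recall/TPR, specificity,
F-measure, G-means = √(TPR·specificity), FNR = 1 − TPR (the published
FNR formula is printed self-referentially; every printed TPR/FNR pair
confirms the 1 − TPR reading), and rank-based AUC on the renormalised
melanoma score p₁/(p₀+p₁).  Zero-denominator ratios are reported as 0
and flagged.

Generator quality: unbiased RBF-kernel MMD² with median-heuristic
bandwidth (clipped at 0 — the unbiased statistic can dip negative for
identical samples); a k-NN (k = 5) estimator of KL(real‖fake), clipped
at 0; sliced Wasserstein-1 with 64 seeded random projections and exact
1-D transport per slice; and a Mode Score computed from an oracle
posterior over mixture modes — on synthetic fixtures the oracle is hard
nearest-mode assignment from the known mixture, so no trained
classifier is needed.  A caveat the test suite surfaces: with a hard
(one-hot) posterior the Mode Score algebraically reduces to
exp(entropy of the fake mode-marginal), so it separates collapse
(score → 1) from coverage (score → e^H) but cannot reward fidelity —
a diffuse generator that spreads over all modes can outscore a sharper
one whose mode marginal is mildly skewed.

## Desk-scale problem sizes

The directional suites run at: ring fixture n = 4000 (mode-collapse
comparison, 5 seeds per arm, λ_r ∈ {0, 0.5}), n = 2000 for the
semi-supervised-gain comparison (5 paired seeds), hidden width 32 and
batch 128 for those fixtures, epochs 64 (the lower bound of the legal
range); optimizer benchmarks use 20 bees × 200 cycles × 10 seeds.

## Known limitations

- On the well-separated ring fixture the λ_r = 0 baseline does not
  actually mode-collapse at desk scale (its mode histogram stays near
  uniform, it is merely diffuse), so the reconstruction benefit shows up
  robustly in MMD (lower in every measured seed) but not in the hard-
  oracle Mode Score, for the algebraic reason above.
- The autodiff engine is scalar-loop-free but Python-dispatched; it is
  sized for desk-scale MLPs, not convolutional backbones.
- The VGG-16 extractor is an interface only; no pretrained weights ship
  and no image I/O is implemented.
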