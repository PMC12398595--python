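# melssgan

Semi-supervised GAN classification of melanoma feature vectors, with a
mutual-learning artificial-bee-colony (ML-ABC) hyperparameter search.

Early melanoma detection is a screening problem with scarce labels:
expert-annotated dermoscopy images are expensive, while unlabeled images
are plentiful, and a missed malignancy (a false negative) is the costly
error.  Semi-supervised GANs address this by training a discriminator to
classify every sample into c + 1 classes — here melanoma, non-melanoma
and *fake* — so labeled, unlabeled and generated samples all carry
training signal.  `melssgan` implements an enhanced SS-GAN of this form
whose hybrid loss adds four mechanisms to the conventional objective:

    L_D = L_sup + L_usup + λ_c · L_consistency + λ_p · L_pseudo
    L_G = −E_fake log(1 − p_fake) + λ_r · E_x ‖G(D_F(x)) − x‖₂

- a **reconstruction loss** (the generator rebuilds real samples from
  their discriminator features `D_F(x)`), countering mode collapse;
- single-head **self-attention** blocks in both networks;
- **consistency regularisation** between a sample and a noise-augmented
  copy of itself;
- **confidence-thresholded pseudo-labels** (threshold τ) on unlabeled
  rows, restricted to the two real classes.

Each mechanism is a pure configuration switch, so the standard ablation
variants ("without reconstruction", "without attention", …) require no
code changes.  Hyperparameters are tuned by ML-ABC over a random-key
genome in [0,1]^D: an artificial bee colony whose employed/onlooker
update moves the worse of a (current, neighbour) pair toward the better
one, `v = x_worse + φ·(x_better − x_worse)`, φ ~ U(0, F).

The package is aimed at method developers: it runs entirely at desk
scale on synthetic feature data (an imbalanced, multi-modal Gaussian
mixture with a 30 % labeled split that emulates CNN-extracted lesion
features), and exposes the feature-extractor boundary as an interface.
It ships the full evaluation stack: confusion-matrix metrics (F-measure,
G-means, TPR/FNR, AUC) and generator-quality metrics (MMD, k-NN KL,
sliced Wasserstein, Mode Score).

## Worked example

```python
import numpy as np
from melssgan import (ring_mixture_spec, generate_mixture_dataset,
                      make_semisupervised_split, SSGANClassifier,
                      distribution_metrics, nearest_mode_posterior)

spec = ring_mixture_spec()                      # 8 modes, d=16, 30% melanoma
data = generate_mixture_dataset(spec, 2000, seed=1)
semi = make_semisupervised_split(data, 0.3, seed=2)   # 30% keep labels

clf = SSGANClassifier(epochs=64, batch_size=128, hidden_width=32,
                      random_state=0)
clf.fit(semi.features, semi.labels)             # y == -1 marks unlabeled

val = clf.history_[-1].val_metrics
print(f"validation F-measure: {100*val.f_measure:.2f}%  "
      f"G-means: {100*val.g_means:.2f}%  FNR: {100*val.fnr:.2f}%  "
      f"AUC: {val.auc:.3f}")

masked = semi.labels == -1
recovered = (clf.predict(semi.features[masked])
             == semi.true_labels[masked]).mean()
print(f"accuracy on the 70% unlabeled rows (vs held-back truth): "
      f"{100*recovered:.2f}%")

fake = clf.sample(1000, seed=3)
rep = distribution_metrics(data.features[:1000], fake,
                           mode_assign=nearest_mode_posterior(spec), seed=0)
print(f"generator vs real: MMD {rep.mmd:.4f}  sliced-W1 {rep.wd:.3f}  "
      f"Mode Score {rep.mode_score:.2f} (max 8 modes)")
```

Output:

```
validation F-measure: 100.00%  G-means: 100.00%  FNR: 0.00%  AUC: 1.000
accuracy on the 70% unlabeled rows (vs held-back truth): 100.00%
generator vs real: MMD 0.0318  sliced-W1 0.227  Mode Score 7.56 (max 8 modes)
```

The classifier separates the synthetic mixture perfectly (it is a
well-separated fixture — this demonstrates mechanics, not clinical
performance) and recovers the labels that were hidden from training.
The generator metrics compare 1000 generated feature vectors with real
ones: MMD and sliced-W₁ near 0 mean high fidelity, and a Mode Score of
7.56 out of 8 means the generator covers essentially all lesion-subtype
modes rather than collapsing onto a few.

`SSGANClassifier` is a scikit-learn estimator (`get_params`/`clone`/
pipelines all work).  The same functionality is scriptable:

```
melssgan simulate --config config.yaml --seed 3 --out run/
melssgan train    --config config.yaml --seed 3 --out run/
melssgan evaluate --config config.yaml --seed 3 --out run/
melssgan ablate   --config config.yaml --seed 3 --out run/   # 6-row table
melssgan tune     --space discriminator --bees 10 --cycles 5 --seed 3 --out run/
```

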