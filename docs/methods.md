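# Methods

## The problem

Multi-label classification of grayscale medical-style images (the motivating
setting is thoracic-disease recognition in chest radiographs): each image may
carry several positive findings at once, positives are rare for some classes,
and a model trained at one institution is deployed at another whose images
differ in aspect ratio, framing and noise. `patchvib` implements a
feature-selection mechanism — a patch-level variational information
bottleneck — inside a complete multi-scale classifier, together with a
synthetic benchmark that reproduces the statistical structure of the problem
so that every component is testable on a laptop CPU with no data download.

## Patch-level variational information bottleneck (P-VIB)

A conventional variational information bottleneck flattens a feature tensor
into a vector, predicts a Gaussian posterior q(z|x) = N(mu, diag(sigma^2)),
and samples z = mu + eps * sigma with eps ~ N(0, I). Flattening destroys the
spatial layout, so the layer can only sit immediately before a classification
head.

The patch-level variant keeps the layout. Given a feature map
F in R^{C_l x W_l x H_l} at pyramid scale l, two parallel 3x3 same-padded
convolutions predict mu_l and log sigma_l at *every spatial position and
channel*; sampling happens per position:

    z_l[j, k] = mu_l[j, k] + eps[j, k] * sigma_l[j, k],   eps ~ N(0, 1) i.i.d.

Because both outputs are feature maps of the input's spatial shape, the layer
drops in anywhere in a CNN. Positions whose posterior collapses to the
standard-normal prior carry no information downstream — the KL penalty below
therefore performs *spatial* feature selection: only informative patches keep
a signal.

The per-scale feature-selection loss is the mean over channels and positions

    L_fea,l = (1/(C_l W_l H_l)) * sum_{j,k} [ mu_{j,k}^2 + sigma_{j,k}^2
                                              - 2 log sigma_{j,k} - 1 ],

summed over the active scales. Each summand is exactly **twice** the
Gaussian KL divergence KL(N(mu, sigma^2) || N(0,1)); the factor is kept as
stated because it is absorbed by the trade-off weight beta. A quadrature
oracle (`kl_oracle`, adaptive integration of p log(p/q)) verifies the closed
form in the test suite to 1e-6 relative error.

Design points the formulation leaves open, and how they are resolved here:

* **sigma positivity** — the second convolution predicts log sigma and
  sigma = exp(log sigma), with log sigma clamped to [-10, 10] for numerical
  safety. The clamp keeps the `2 log sigma` term exact.
* **sigma semantics** — sigma is treated as a standard deviation; that is
  the only reading under which the penalty above is (twice) the Gaussian KL.
* **inference** — evaluation uses the posterior mean, z = mu (no sampling);
  `mode="train"` on the forward pass re-enables Monte-Carlo sampling for
  study.
* **latent width** — the latent channel count defaults to the input channel
  count so the layer is shape-preserving end to end; it is configurable.
* **initialization** — the mean path starts with std 1/sqrt(9 C_l) weights
  and zero bias; the log-sigma path starts near zero so sigma starts near 1
  and the initial KL is small.

## Classification loss and combined objective

Per scale l, with sigmoid confidence p_c and binary label y_c over C
classes, the bias focal loss is

    L_cls,l = (1/C) sum_c [ -alpha (1-p_c)^{lambda_l} y_c log p_c
                            - (1-alpha) p_c^{lambda_l} (1-y_c) log(1-p_c) ],

averaged over the mini-batch (the batch reduction is an arithmetic mean, so
the value is batch-size invariant). `alpha` (default 0.4) biases the
trade-off between the positive and negative terms — the class-imbalance
control; `lambda_l` (defaults (0.5, 0.3, 0.1) for scales (P2, P3, P4))
focuses the loss on hard examples, focal-style. With lambda = 0 and
alpha = 1/2 the loss is exactly half the mean binary cross-entropy, a
degeneration the tests pin to 1e-10.

`lambda_l` enters as an *exponent*, following the loss's printed definition;
because the per-scale values read equally naturally as multiplicative scale
weights, a documented `lambda_mode="multiplier"` variant is provided for
sensitivity study and is not used by any default.

Probabilities are clamped to [1e-7, 1 - 1e-7] before logarithms.

The combined objective is

    L = sum_l L_cls,l + beta * sum_l L_fea,l,

beta default 0.1 (the value selected by the upstream sweep over
{0.01, 0.05, 0.1, 0.15}); beta = 0 recovers the VIB-free baseline exactly.

## Architecture

`backbone -> [P-VIB] -> [ECA neck] -> [P-VIB] -> CSRA head`, per scale, at
pyramid scales P2/P3/P4 (strides 8/16/32). Every bracketed block is
switchable from `ModelConfig` alone, so the ablation lattice (±neck,
±multi-scale, VIB before vs after the neck, VIB off) requires no code
changes. P4 is always active; the single-scale ablation keeps only P4.

* **Backbone (`small_cnn`)** — a deliberately compact stride pyramid for
  CPU-scale experiments: a 7x7 stride-4 patchify stem, then three 3x3
  stride-2 stages, channels (16, 32, 64, 128), each stage followed by group
  normalization (per-sample statistics; identical in train and eval) and
  ReLU. The normalization is load-bearing: it is what lets a from-scratch
  network reach high AUC within ~300 Adam steps at the small default
  learning rate. Named large pretrained backbones (`res2net50`, `resnet50`,
  `densenet121`) are registry hooks (`register_backbone`) for users who
  bring an implementation; they are not bundled.
* **ECA neck** — efficient channel attention: global average pool to a
  channel descriptor, a 1D convolution across channels whose odd kernel size
  follows the published adaptive rule k = odd(|log2 C + 1| / 2), a sigmoid
  gate, and channel-wise rescaling. Spatial content is untouched; each
  channel is multiplied by a gate in (0, 1).
* **CSRA head** — class-specific residual attention: a 1x1 convolution
  scores every class at every position; the logit is the spatial mean score
  plus `residual_weight` times a temperature-softmax attention pooling of
  the same score map. With residual weight 0 the head reduces to a
  global-average-pool linear classifier. Defaults are tuned for the
  desk-scale regime rather than the large-pretrained-backbone conventions
  (temperature 1.0, residual weight 0.1): small localized lesions on large
  feature maps dilute the mean score, so the package defaults to sharper
  attention (T = 0.5) with a full-weight residual (1.0). The head bias
  starts at logit(`head_bias_prior`, default 0.15) instead of zero — on
  imbalanced multi-label targets a zero bias forces the first chunk of
  training to do nothing but pull the initial p = 0.5 outputs down to the
  base rates; prior calibration skips that phase. All three are
  configurable.
* **Scale fusion** — per-scale sigmoid probabilities are averaged at
  inference (configurable to a single scale). How the per-scale heads merge
  into one prediction is not specified by the formulation; the arithmetic
  mean is this package's choice, chosen for symmetry and because it keeps
  each head individually calibrated against the same labels.

Preprocessing follows the standard recipe: resize to 256/224 of the crop
size, random crop (center crop at evaluation), horizontal flip with p = 0.5,
contrast jitter in [0.9, 1.1], then normalization to mean 0.5 / std 0.25.
Saturation and hue jitter are identity operations on single-channel images
and are therefore omitted.

## Evaluation

Per-class AUC is the rank-based Mann-Whitney statistic (ties count one
half), which equals the trapezoidal area under the empirical ROC — the test
suite checks this identity to 1e-12 and cross-checks scikit-learn. The
macro average weights each class equally; the **micro** average pools every
(sample, class) pair of the defined classes into one binary problem — the
standard construction, stated explicitly because macro and micro can differ
substantially under imbalance. Classes with single-valued label columns have
no defined AUC; they are excluded from both averages and reported in
`excluded_classes`. Early stopping monitors micro AUC by default
(configurable to macro).

## Training

Adam, learning rate 1e-4, batch size 64, multiplicative x0.9 decay every 2
epochs, 20 epochs by default; the batch size of 64 follows the reference
recipe (its "patch size 64" is read as the mini-batch size — the value sits
among the other optimizer settings and no image-patch operation of that size
exists in the pipeline). After every epoch the validation AUC is computed;
the best-scoring snapshot is kept and returned — never the final epoch. One
master seed fans out through independent `SeedSequence` streams to weight
initialization, shuffling, augmentation and the reparameterization noise, so
a run is exactly reproducible from (configs, seed). A non-finite loss aborts
with a diagnostic rather than training on.

`beta_sweep` and `fraction_sweep` wrap the loop for the two standard
studies: the trade-off-weight sweep (with an optional VIB-free baseline row)
and the training-set-fraction generalization experiment over source and
shifted-domain test sets.

## The synthetic benchmark

The generator emulates the three statistical properties of the motivating
datasets, not their appearance:

* **co-occurrence** — binary latent factors z_m ~ Bernoulli(1/2) drive
  label activation p_c = rate_c + sum_m loading[m, c] (z_m - 1/2); marginals
  equal `positive_rate` exactly and classes sharing a factor co-occur with
  covariance loading_1 * loading_2 / 4. Defaults: 4 classes, 2 factors,
  rates (0.3, 0.3, 0.15, 0.05) — the last class is deliberately rare.
* **imbalance** — the per-class rates above, configurable.
* **domain shift** — the deployment variant stretches the anatomy
  horizontally by 1.22 (the width-to-height ratio gap between the motivating
  source and deployment datasets), translates it off-center by 8% of the
  width, and adds sigma = 0.05 Gaussian noise; labels are untouched.

Images are 224x224 grayscale by default: a vertical-gradient background with
a central bright "anatomy" ellipse and a per-image low-frequency random
field, one additive Gaussian-profile lesion blob per active class at a
class-characteristic location (with small center jitter, radius and texture
variation), then speckle noise. A template-matching probe (correlation with
each class's canonical blob) certifies the task is solvable (per-class AUC
> 0.95) before any learning — so AUC-based checks measure the learner, not
the generator.

What the generator does **not** model: real anatomy or pathology appearance,
label noise/uncertainty, scanner physics, patient-level correlation between
images, or resolution heterogeneity. Passing tests demonstrate that the
method's machinery works and that the bottleneck's regularization behaves
directionally as expected under a controlled domain gap; they say nothing
about clinical performance.

## Numerical choices

* log sigma clamped to [-10, 10]; probabilities clamped to
  [1e-7, 1 - 1e-7]; group-norm epsilon 1e-5.
* KL quadrature oracle: adaptive quadrature over mu ± 12 sigma,
  absolute/relative tolerance 1e-12; an estimated error above 1e-6 raises.
* AUC ties: average ranks (half credit); degenerate classes return NaN
  rather than raising.
* The autodiff engine computes in the dtype of its inputs: float32 for
  training throughput, float64 in gradient-check tests (central finite
  differences are the independent oracle, tolerance 1e-4 relative).
* Checkpoints are single `.npz` files carrying all weights plus the JSON
  model configuration; reload is bit-exact.

## Problem sizes used by the test suite and acceptance script

The default benchmark study — 2000 train / 500 val / 500 test images at
224 px, 10 epochs — is the package's reference run and completes in minutes
on one CPU core. The stochastic studies (domain-shift direction over 5
seeds; architecture-grid smoke runs) use 64-px images with a few hundred
samples and 2-4 epochs; the acceptance script's end-to-end study uses 96-px
images with 800/240/240 samples and 6 epochs. These sizes are the package's
chosen desk-scale study conditions; the directional conclusions they support
are scale-free, the absolute AUC values are not.

## Known limitations

* The engine is CPU/numpy only; no GPU path, no mixed precision, no
  distributed training.
* The bundled backbone is intentionally small; results with it are
  desk-scale demonstrations, not comparable to pretrained large-backbone
  numbers.
* Monte-Carlo evaluation (sampling at test time) is exposed but not studied;
  the default deterministic z = mu evaluation is the package's convention.
* The focal exponent reading of lambda_l vs the multiplier reading remains
  genuinely ambiguous in the source formulation; both are implemented, the
  exponent form is canonical here.
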