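# Methods

## Problem and model

`guidegp` predicts the cleavage efficiency of a CRISPR guide RNA (or a
guide–target pair) together with a per-prediction uncertainty.  Activities
are real-valued labels affinely rescaled to [0, 1] (minimum → 0, maximum →
1; the fitted `ActivityScale` makes the map invertible, and labels outside
the training range are *not* clamped at predict time, since clamping would
silently bias calibration).  Sequences are strings over {A, C, G, T},
one-hot encoded with the fixed channel order A, C, G, T (alphabetical); the
same order is used everywhere — model inputs, ALE matrices, sequence logos.

The regressor is a deep-kernel pipeline:

1. **Preprocessor.**  A coordinate-augmented convolution (a normalized
   positional channel is concatenated before the convolution, which helps
   on one-hot sequence data) followed by leaky-ReLU; 1-D for single guides,
   2-D for (2, 4, N) guide–target images.  A stack of four LSTM layers is
   available as an alternative for single-guide inputs.
2. **Hit-or-Miss capsules.**  Five parallel capsules, each
   `linear → batchnorm → sigmoid`, reporting the deviation from the fixed
   center C = 0.5: `O_i(x) = 0.5 − sigmoid(bn_i(W_i x))`.  Outputs lie
   strictly inside (−0.5, 0.5) and form the guide's coordinates in "guide
   space".  Batch normalization is independent per capsule, uses batch
   statistics at train time and running statistics at evaluation.
3. **Two-layer variational GP head.**  Layer 1 maps the flattened capsule
   coordinates to 2 outputs with a linear mean; layer 2 maps those to one
   output with a constant mean.  Each layer carries a stationary RBF-class
   kernel with learned per-dimension lengthscales and an output scale.

## Variational approximation

Each GP layer is represented through a random-Fourier-feature (sparse
spectrum) expansion of its RBF kernel: `phi(x) = sqrt(2 s² / R) [cos(Z x),
sin(Z x)]` with the R/2 rows of `Z` drawn once from `N(0, diag(1/l²))` and
kept fixed; lengthscales `l` and outputscale `s` are learned by
backpropagation through `phi`.  The layer function is `f(x) = m(x) +
phi(x)ᵀw` with a mean-field Gaussian variational posterior `q(w) = N(mu,
diag(sigma²))` against a standard-normal prior, giving a closed-form KL
term.  We chose this representation over inducing-point sparse GPs because
it needs no Cholesky factorizations inside the training loop while
satisfying the same evidence-lower-bound (ELBO) contract; with 128 features
per layer the kernel approximation error is far below the label noise at
the problem sizes involved.

Training maximizes the doubly stochastic ELBO.  The first layer is resolved
by reparameterized *marginal* sampling per data point (`f1 = mu1(x) +
sqrt(var1(x)) ε`); conditional on that draw the expected Gaussian
log-likelihood of the output layer is computed in closed form
(`E_q[log N(y | f, σ_n²)] = log N(y | mu2, σ_n²) − var2 / 2σ_n²`).  The
closed form matters in practice: a purely sampled estimator leaves so much
gradient noise on the variational variances that they never tighten within
the fixed 60-epoch budget, which inflates the predictive spread and ruins
interval calibration.  The observation noise σ_n² is a learned softplus
parameter (floor 10⁻⁶).  The optimizer minimizes −ELBO (per data point,
with the KL scaled by 1/n_train); the optional combined loss adds
α·MSE(y, ŷ) with α = 0.5, where ŷ is the mean of the sampled predictive
means.

## Training and prediction

Adam, initial learning rate 0.01, multiplied by 0.9 every tenth epoch, 60
epochs, batch size 192.  A single integer seed drives parameter
initialization, epoch shuffling and every Monte-Carlo draw, so training is
exactly reproducible (tolerance 10⁻⁶ on parameters across platforms; same
machine is bitwise).  A non-finite loss aborts with a diagnostic rather
than continuing silently.

The encoder (convolution + capsules) receives decoupled weight decay
(default 0.2 at these small layer sizes); GP hyperparameters, variational
parameters and the likelihood noise are not decayed.  This regularization
is what makes the predictive intervals honest: without it the encoder
partially memorizes label noise, the learned σ_n tracks the too-small
training residuals, and held-out coverage collapses.  The default encoder
is deliberately small (4 conv channels, 5 capsules × 4 dimensions) for the
same reason; both choices are configurable.

Prediction draws S samples (default 64) per input: a marginal draw of the
first layer, a marginal draw of the second given the first, plus Gaussian
observation noise.  The reported mean/std are the sample mean and sample
standard deviation (ddof = 1), so the interval reflects epistemic and
observation uncertainty together; std is strictly positive and S ≥ 2 is
enforced.

## Calibration metrics

`coverage_rho(Y, Ŷ, σ, M)` is the fraction of held-out labels inside the
closed interval `Ŷ ± Mσ`; at M = 1, 2, 3 it is compared with the Gaussian
nominal levels 0.68 / 0.95 / 0.997 (ρ₆₈, ρ₉₅, ρ₉₉.₇).  Both endpoints are
closed — for continuous predictors the choice is measure-zero.  r² is the
determination coefficient 1 − SSres/SStot (it can be negative), PCC/SCC are
Pearson/Spearman correlations.  Cross-validation uses plain random k-fold
splits (seedable); the learning-curve harness trains on *nested* subsets
against one fixed test split so curves are comparable.

## Synthetic data generator

The generator produces the study conditions for every test: sequences
i.i.d. uniform over {A,C,G,T}^N (a GC-biased option exists), activity
`f(seq) = sigmoid(Σ_p w[base_p, p])` with standard-normal per-base weights
on the five PAM-proximal (3′-terminal, Cas9-like seed) positions and zero
elsewhere, and heteroscedastic Gaussian label noise whose sd is a
deterministic hash of the sequence mapped uniformly into [0.05, 0.15].
Hash-based noise keeps σ(seq) reproducible independent of the data seed, so
the calibration target is well-posed.  Labels are rescaled to [0, 1]; the
ground-truth f and σ are returned on both scales.  Pair datasets mutate
guides at 0–6 positions and damp activity by `exp(−Σ penalty_p)` with a
larger penalty for seed-region mismatches.

What this emulates — and what it does not: the generator reproduces the
*statistical* structure the model assumes (seed-region-dominated sequence
effect, heteroscedastic label noise, mismatch attenuation), not the
biophysics of real cleavage data (no GC-content nonlinearity, no position
interactions, no chromatin context, no realistic label distributions).
Passing tests therefore demonstrate correct inference under the model's
own assumptions, not performance on experimental datasets.

With noise sd uniform in [0.05, 0.15] and a homoscedastic Gaussian
likelihood, perfectly fitted intervals would cover about 72% / 94% / 99% at
1/2/3σ rather than exactly 68/95/99.7 — a deliberate, realistic mismatch
the acceptance bands accommodate.

## Interpretation

For one-hot inputs every feature is binary, so accumulated local effects
reduce to a centered two-level difference: each feature is forced to 0 and
to 1 over a reference sample of M random synthetic sequences (M = 10 000 by
default), and the two level means are centered by the empirical level
frequencies.  Both model outputs — predictive mean and predictive
variance — are explained.  Logos apply a temperature softmax along the base
axis of a (4, N) effect slice; columns are exactly stochastic, t → 0 gives
the argmax base, t → ∞ the uniform column.  Guide-space coordinates are
the flattened capsule outputs; 2-D embedding supports PCA and UMAP, and
clustering is scipy agglomerative linkage cut at cophenetic distance 2
(single linkage by default, Ward optional — the flat-cluster structure can
depend on this choice).

## Genome pipeline

The scanner matches a PAM mask (Cas9 `N₂₁RG`, Cas12a `TTTN₂₁`, or custom
over {A,C,G,T,R,N}) over both strands; minus-strand hits carry
reference-strand coordinates and the reverse-complemented sequence.
Windows touching non-ACGT characters (N runs in real chromosomes) are
skipped with a logged warning.  Off-targets of a guide are mask-matching
windows with protospacer Hamming distance ≤ 6; PAM positions must match the
mask exactly and never count as mismatches.  Scored tables sort by
predicted mean descending with deterministic tie-breaking (variance
ascending, then start).  When a pair model scores a genomic site on its
own, the site sequence occupies both channels; when scoring a guide against
an off-target site, the guide is embedded at the mask's N positions and the
site's PAM is copied, so both channels have equal length.  Off-target
categories split on strict thresholds: mean < 0.15 is "low efficiency",
variance < 0.015 is "low variance"; equality falls in "high".  Annotation
coordinates are 1-based inclusive externally (genome-browser convention),
0-based half-open internally; output tables are 0-based with a `--one-based`
flag.

## Numerical choices and limitations

- Autodiff core: a minimal reverse-mode engine over float64 numpy arrays
  (the only primitives the model needs); gradients are verified against
  central finite differences in the test suite.
- Sigmoid is clipped at ±500 before exponentiation; capsule outputs can
  reach ±0.5 only in exact float saturation, far outside normal operation.
- Batches with fewer than 2 examples are skipped (batch statistics are
  undefined).
- Problem sizes in the test suite (n = 3000 for the calibration study,
  1200–2000 for recovery checks, reduced architectures in unit tests) were
  chosen so the full suite completes in a few minutes on one CPU core while
  keeping every statistical check comfortably powered.
- Known limitations: homoscedastic likelihood (see above); no GPU path; no
  bulge-type off-targets (mismatches only); checkpoints store weights and
  configs but not optimizer state, so training cannot be resumed mid-run.
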