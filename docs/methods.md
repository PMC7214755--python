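# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the evaluation protocol implemented in `kinlatent`,
including the places where the design was genuinely open and what the
package chose.

## The two dimensionality-reduction models

**PCA.**  Fit by singular value decomposition of the mean-centered sample
matrix rather than eigen-decomposition of the covariance; the two are
algebraically identical (eigenvalues are squared singular values over
m−1) but the SVD is numerically stabler.  The economy SVD is used whenever
samples outnumber channels, so no n×n matrix is ever formed.  Loadings
form a complete orthonormal basis even on rank-deficient data (trailing
eigenvalues zero).  Because singular vectors are defined only up to sign,
each loading column is flipped so its largest-magnitude element is
positive, making models reproducible across numerics backends.  Encoding
is projection of centered data onto the first k loadings; decoding adds
the mean back.

**Autoencoder (nAEN).**  A three-hidden-layer autoassociative network in
Kramer's design: nonlinear mapping layers (tanh by default; sigmoid and
relu available), a *linear* bottleneck of width k whose columns are the
coding units, and a linear output layer.  The mixed linear/nonlinear
design makes linear structure easy to represent — with identity
activations the network reduces exactly to a linear autoencoder, whose
optimal k-dimensional reconstruction spans the PCA subspace (this limit is
asserted in the tests).  Loss is mean squared reconstruction error over
samples and channels; MSE is the loss that VAF, the evaluation metric,
directly rewards.  Training is full-batch gradient descent with the ADAM
optimizer (β₁ = 0.9, β₂ = 0.999, ε = 1e-8 — the optimizer's published
defaults), learning rate 0.01, 10,000 steps, no regularization.  These
training defaults sit at the operating point where a cross-validated
sweep (`hyperparameter_sweep`, grid learning rate ∈ {0.001, 0.01, 0.025,
0.05} × activation ∈ {tanh, relu, sig}) shows stable performance for this
architecture on kinematic data; the largest rate (0.05) is the unstable
corner.  Backpropagation is hand-derived and verified against central
finite differences to < 1e-5 relative error for every parameter block and
all activations.

Open parameters the architecture itself does not pin down, with the
package's defaults:

- hidden width `h` = 10 (config knob; behaviour is insensitive over
  h ∈ {5, 10, 20} and the tests are written to hold across that range);
- initialization: seeded Glorot-uniform weights ±√(6/(fan_in+fan_out)),
  zero biases — scale-balanced so neither tanh saturation nor vanishing
  gradients dominate at step 0;
- divergence guard: training aborts with an error naming the step if the
  loss becomes non-finite, rather than returning garbage.

## Synthetic generator

Real data-glove corpora of labeled gesture repetitions are rarely
deposited, so experiments run on a generator whose ground truth is known:

- a `latent_dim`-dimensional (default 2) latent process drives
  `n_channels` = 20 channels at 100 Hz;
- each movement class (default 10, emulating a sign-language gesture set)
  has a target posture in latent space, scaled by `class_separation`;
- each trial ramps sigmoidally from the REST origin to the class target,
  holds 3 s (tagged ACTIVE — matching cue-based protocols where the
  participant maintains the gesture), and ramps back; REST hold 2 s, ramps
  0.5 s, tagged REST;
- repetitions are humanized: per-trial target jitter (sd 0.05 latent
  units) and a slow within-trial latent wander (smoothed noise, sd 0.05)
  model imperfect, drifting holds;
- channels are `x = G(z) + ε` with i.i.d. Gaussian sensor noise
  (`noise_sd` = 0.02, ≈2% of the unit signal scale — the resolution order
  of resistive bend sensors).

`G` is a fixed seeded map.  In linear mode it is a mix through unit-norm
random channel directions, so noise-free data lie exactly in a
`latent_dim` plane: a linear method must be exact there, and the tests
assert it.  In nonlinear mode each mixed channel additionally passes
through a smooth bounded sinusoidal warp `sin(g_c u + φ_c)` with seeded
per-channel gain and phase (`warp_amplitude` = 2.0 scales the gains).  A
*non-monotone* warp is deliberate: monotone saturations of a 2-D linear
mix retain ~99% of their variance in a 2-plane (the arcsine-law effect for
quantized/saturated Gaussian mixes), which would make the linear and
nonlinear modes nearly indistinguishable.  Sinusoidal channel responses —
a channel rising and falling again within one coordinated excursion, as
coupled joints do — bend the manifold genuinely: at the default amplitude,
two principal components reconstruct noise-free nonlinear data in the low
80s percent VAF, the regime reported for two PCs on real whole-hand
kinematics, while the manifold's intrinsic dimension stays 2.

What the generator does **not** emulate: anatomical joint-angle ranges and
couplings, glove sensor cross-talk, trial-to-trial fatigue or learning
effects, and class-dependent movement durations.  Passing tests therefore
demonstrate correct behaviour of the methods on data with known
low-dimensional (non)linear structure — not performance claims about any
particular real glove corpus.

## Preprocessing

First-order Butterworth low-pass, 10 Hz cutoff, designed at the
recording's sample rate.  Application is zero-phase (forward–backward) by
default: it introduces no lag that would misalign the REST/ACTIVE labels,
at the cost of squaring the magnitude response (gain 0.5 rather than 1/√2
at the cutoff — asserted in the tests).  A causal single-pass mode exists
for streaming-faithful processing.  Only ACTIVE samples are analyzed.
Normalization divides by the single absolute maximum over all channels and
samples of the dataset, preserving inter-channel amplitude ratios;
normalization precedes the 80/20 holdout split, which matches the
protocol this pipeline reproduces, and a train-only-scale option exists
for leakage-free workflows.  The holdout is sample-level by default (again
protocol-faithful); a trial-level option avoids leaking within-trial
autocorrelation.

## Evaluation protocol

Per participant and latent size k: VAF is computed on the held-out 20% of
samples; dimension variance and separability are computed on the entire
dataset (train + test combined).  This split of evaluation sets is
protocol-faithful rather than best practice, and is flagged as such.
Separability uses an unregularized multinomial logistic classifier
(L-BFGS, gradient tolerance 1e-6, 5,000-iteration cap; on separable
classes the weight norm diverges but the decision boundary stabilizes well
before the cap).  Folds are stratified by class; a trial-grouped mode
exists.  Argmax ties (measure-zero in practice) resolve to the lowest
class index via the underlying solver.

Cross-participant statistics: metrics like VAF and accuracy are bounded
percentages and routinely fail Anderson–Darling normality screening, so
comparisons use rank tests.  The Wilcoxon signed-rank test uses an exact
null distribution for n ≤ 25 pairs — a dynamic program over signed-rank
sums with mid-ranked ties (ranks doubled to stay integral), which keeps
the exact branch valid where a permutation-free enumeration would refuse
ties — and the normal approximation with continuity and tie corrections
above.  Zero differences are dropped (the common convention).  The
Anderson–Darling p-value uses the Stephens small-sample-corrected
approximation for the composite-normal case, since the underlying library
exposes only critical values.  The pipeline's post-hoc family is exactly
four contrasts (VAF at the smallest k; dimension-variance range;
latent-vs-reconstructed separability per method), Bonferroni-adjusted to
0.05/4 = 0.0125; the family is enumerated in the report itself.

## Problem sizes

The full protocol (10 participants × 10 classes × 10 trials, 10,000
training steps, five latent sizes) is the pipeline's default
configuration.  The test suite exercises the same protocol shape at
reduced size — 6 classes × 3 trials with 1.5 s holds and 2,000 training
steps, five seeds standing in for participants — chosen so the complete
suite runs in a few minutes while every qualitative contrast (nonlinear
advantage, gap decay in k, variance-spread ordering, separability
pattern) is still resolved with margin.

## Known limitations

- The autoencoder is a fixed 4-layer topology; deeper, convolutional, or
  variational variants are out of scope, as is early stopping (training
  runs a fixed step count).
- Sample-level holdout on autocorrelated time series overstates test
  performance; use the trial-level split option when that matters.
- The generator's arbitrary units mean absolute VAF values on synthetic
  data should not be read as predictions for any specific glove hardware.
- `range_of_dimension_variance` summarizes a profile by max−min only; two
  profiles with equal range can differ in shape.
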