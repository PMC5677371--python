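# Methods

## Problem setting

An electronic nose (e-nose) is an array of cross-sensitive metal-oxide gas
sensors plus a pattern-recognition stage.  The task here is four-class
discrimination of wound-infection odor (uninfected control, *P. aeruginosa*,
*E. coli*, *S. aureus*) from sensor response curves.  Labeled infection
recordings are scarce and expensive (20 per class, 80 total), while
unlabeled recordings of cheap pollutant gases (benzene, formaldehyde,
acetone, ethyl alcohol; 132 + 203 + 153 + 164 = 652 by default) are
plentiful.  Self-taught learning uses the unlabeled pool — whose classes
are disjoint from the target classes — to learn a representation that is
then applied to the labeled task.

## Synthetic data generator

No public recordings exist for this problem, so `enose_stl.simulate`
generates study-shaped data.  Each recording is 1201 samples at 1 Hz:
baseline (0–180 s, clean air), exposure (180–480 s, analyte), recovery
(480–1200 s, clean air).  Sensor s responds with first-order kinetics
toward `baseline_s + A_s`:

    exposure:  v(t) = b + A (1 - exp(-(t-180)/rise_tau))
    recovery:  v(t) = b + A (1 - exp(-300/rise_tau)) exp(-(t-480)/decay_tau)

with i.i.d. Gaussian noise added pointwise and voltages clipped at zero.
Defaults: `rise_tau` 25 s, `decay_tau` 90 s (recovery of MOS sensors is
slower than uptake), `noise_sd` 0.02 V against baselines drawn once per
dataset from U(0.4, 0.6) V and amplitudes of 0.3–1.8 V.  The per-class and
per-gas amplitude archetypes are free parameters of the study design; they
were fixed once as distinct five-sensor patterns of comparable magnitude,
with the infection archetypes inside the span of the gas archetypes so
that a basis learned on gases is in-distribution for the transfer step.

What the generator does *not* emulate: sensor drift, temperature/humidity
covariates, concentration sweeps within a gas, correlated noise, real MOS
adsorption physics.  Passing tests therefore demonstrate the pipeline's
internal correctness and its qualitative behavior under controlled
separability and noise — not field performance on animal data.

## Features

Five scalars per sensor, all computed after subtracting the per-sensor
baseline (mean of the last 60 s of the baseline phase, robust to startup
transients): maximum steady-state response over the exposure window;
maximum forward difference over exposure (rising slope, V/s); maximum
magnitude of negative forward difference from the exposure-end sample
onward (falling slope, reported positive); trapezoidal integral of the
exposure window; and the maximum absolute detail coefficient of a
Daubechies-4 DWT at level 3 of the full signal.  Slopes use raw 1 Hz
differences with no smoothing.  The wavelet family, level and
max-abs-coefficient reduction are package choices (config-exposed); the
integral covers the exposure phase only.

An n × n matrix (rows = first n features in the order above, columns =
first n sensors; n ∈ {3,4,5}) is flattened row-major into x ∈ R^(n²).
Datasets are min–max scaled to [0,1] per coordinate — the range a sigmoid
autoencoder can reproduce — with bounds fitted on the union of the
unlabeled pool and the labeled training split only; constant coordinates
map to 0.

## Sparse autoencoder

Single hidden layer, sigmoid activations everywhere, trained to reproduce
its input by full-batch gradient descent on

    J_sparse = (1/k) Σ_i ½‖h(x_i) − x_i‖² + (μ/2)(ΣW₁² + ΣW₂²)
               + β Σ_j KL(ρ ‖ ρ̂_j),

KL(ρ‖q) = ρ log(ρ/q) + (1−ρ) log((1−ρ)/(1−q)), where ρ̂_j is hidden unit
j's mean activation over the whole batch.  Defaults: μ = 3e-3, β = 3,
ρ = 0.01, hidden width 10.  Weight decay covers weights only, never
biases.  ρ̂ is clamped to [1e-12, 1−1e-12] before logs and divisions.
Weights initialize uniformly in ±sqrt(6/(fan_in+fan_out+1)) with zero
biases — near zero, but asymmetric enough to break hidden-unit symmetry.
The learning rate (0.5) and iteration budget (400) are package defaults,
config-exposed; a non-finite cost raises a divergence error naming α
rather than clipping silently.  Backpropagation carries the sparsity term
into the hidden delta (β(−ρ/ρ̂ + (1−ρ)/(1−ρ̂)), broadcast per unit), which
is the exact gradient of the batch objective; a central-difference checker
(ε = 1e-4, relative discrepancy |g_a − g_n| / max(1, |g_a|+|g_n|))
verifies every coordinate of the unrolled θ to ≤ 1e-6 on small instances.

## Transfer step

Each normalized labeled vector is replaced by its full reconstruction
x̂ = f(W₂ f(W₁x + b₁) + b₂) — output layer, not the hidden code — with
labels, counts and order preserved.  The hidden-code variant used by
classic self-taught learning is available as `representation="hidden"`,
default off.

### A structural limitation worth knowing

With the defaults above, the initial gradient of the sparsity penalty
(β·s₂·KL(0.01‖0.5) ≈ 19 for 10 hidden units) exceeds the reconstruction
gradient on [0,1]-scaled features (≈ 0.12) by two orders of magnitude.
Batch gradient descent therefore drives every hidden unit into sigmoid
saturation at ρ within a few iterations; the factor a₂(1−a₂) ≈ 0.01 then
freezes the encoder, and near convergence the reconstruction is
essentially sample-independent (the test suite asserts across-sample
reconstruction variance below 1e-12 after 3000 iterations; the collapse
is not specific to the width of 10).  During the finite training transient the
reconstruction acts as a small, approximately affine, low-rank transform
of the input.  Consequence: the self-taught representation preserves
class structure well enough not to degrade classification on the
moderate-noise benchmark, but it cannot denoise, and in high-noise /
few-label regimes it measurably *underperforms* raw features.  The test
suite asserts the non-degradation property and carries one deliberately
failing check documenting the absent high-noise advantage; re-normalizing
the reconstruction before classification was evaluated and does not
change this, so it is not done.

## Optimizer

Canonical quantum-behaved PSO: per-dimension attractor
p = φ·pbest + (1−φ)·gbest and position update
x ← p ± α_ce·|mbest − x|·ln(1/u), u, φ ~ U(0,1), mbest the mean personal
best, α_ce linearly decreasing 1.0 → 0.5.  Defaults 30 particles, 300
iterations.  Positions are clipped to the search box; u is sampled in
(0, 1] so the logarithm stays finite; the best-so-far trace is monotone
and every run is bit-reproducible from its seed.  The class is pluggable
so enhanced variants can be swapped in.

## Classifiers and tuning

*RBF network*: K Gaussian kernels at seeded k-means centers
(scipy `kmeans2`, '++' init; if K is not realizable because the training
set has fewer distinct points, the distinct points themselves are used —
they are the k-means fixed point), shared width σ, ridge least-squares
output layer against one-hot targets, argmax decision with ties broken
toward the lowest class index.  With K = n distinct points and no ridge
the Gaussian design matrix is nonsingular and the network interpolates
exactly.

*PLS-DA*: NIPALS PLS2 of centered features on centered one-hot
indicators, with deflation of both blocks (handles collinear columns;
extraction stops early on an exhausted residual).  With components equal
to the feature rank the coefficients reproduce multivariate least
squares; scikit-learn's `PLSRegression` serves as an independent
cross-check in the tests, never as the implementation.

*Tuning*: QPSO minimizes 5-fold stratified cross-validated
misclassification on the 60-sample training split (the test split never
enters tuning).  RBF searches (log₁₀σ ∈ [−2, 1.5], log₁₀λ ∈ [−8, 0],
K ∈ [2, 25]); PLS-DA searches the rounded continuous relaxation of the
component count.  Hyperparameter sets that fail to fit score as total
error.  Inside pipeline runs the tuning swarm uses 12 particles × 40
iterations — a desk-scale budget chosen because the CV objective
plateaus well within it on these 60-sample problems — while the
optimizer's own defaults remain 30 × 300.

## Splits, counts, experiment grids

The labeled pool (4 × 20) is split stratified 15 train / 5 test per class
(60 / 20).  `run_pipeline` derives every stage seed from one master seed
via `SeedSequence`, so a single integer reproduces a run bit-for-bit; it
reports train/test accuracy for the raw and the self-taught branch from
the same split and tuning protocol.  `run_grid` sweeps matrix dimension
{3,4,5}, unlabeled-pool size, and hidden width with repeats, records
per-cell failures without aborting, and summarizes per-cell means.

## Benchmark regimes used by the tests

Moderate-noise benchmark: default archetypes, `noise_sd` 0.25, dim 3,
15/5 split, hidden 10, full 652-sample pool, 8 seeds.  High-noise /
few-label regime: `noise_sd` 0.8, 5/5 split, dim 3, 6 seeds.  Both were
fixed from the simulator's physical scale before the end-to-end
comparisons were run.  Unit-level checks use a reduced pool
(4 × 25 unlabeled) purely to keep runtimes low; counts-sensitive checks
always use the full design (80 labeled, 652 unlabeled).

## Numerical notes

Degenerate inputs: constant feature coordinates scale to 0; zero-variance
feature matrices are rejected by PLS-DA; empty sample lists are rejected
by accuracy; `iterations=0` returns the initialization unchanged.  All
serialization (autoencoder θ, classifiers, scaler) is JSON text with
exact float round-trip.  Known limitations: no sensor drift or
covariates in the simulator; no stacked/denoising autoencoder variants;
no mini-batch training; the "enhanced" QPSO modifications referenced in
the source literature are not publicly specified and are not implemented.
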