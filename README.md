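# enose-stl

Self-taught learning for electronic-nose wound-infection classification.

## The problem

An electronic nose — an array of cross-sensitive metal-oxide gas sensors —
can discriminate wound-infection types (uninfected control,
*P. aeruginosa*, *E. coli*, *S. aureus*) by their volatile metabolites.
The obstacle is data: labeled infection recordings require animal
experiments and are scarce (20 per class), while unlabeled recordings of
cheap pollutant gases (benzene, formaldehyde, acetone, ethyl alcohol) are
abundant.  Self-taught learning bridges the gap: learn a basis θ from the
unlabeled pool with a sparse autoencoder, re-represent the labeled samples
through that basis, and classify the new representation.  This package
implements that pipeline end to end for chemometrics practitioners,
together with a synthetic sensor-array simulator so every stage runs and
is testable offline.

## Method

Each recording (1 Hz; 3 min baseline / 5 min exposure / 15 min recovery)
yields five per-sensor features: steady-state maximum, max rising slope,
max falling slope, exposure integral, and a DWT detail-coefficient
maximum.  An n × n feature-by-sensor matrix (n ∈ {3,4,5}) is flattened to
x ∈ R^(n²) and min–max scaled to [0,1].

The sparse autoencoder (sigmoid, one hidden layer of s₂ units) is trained
on the k unlabeled vectors by full-batch gradient descent on

    J_sparse(W,b) = (1/k) Σᵢ ½‖h(xᵢ) − xᵢ‖²  +  (μ/2) Σ W²
                    +  β Σⱼ KL(ρ ‖ ρ̂ⱼ),

with μ = 3·10⁻³, β = 3, sparsity target ρ = 0.01, and
ρ̂ⱼ the batch-mean activation of hidden unit j.  Backpropagation carries
the KL term into the hidden delta and is verified coordinate-by-coordinate
against central differences (ε ≈ 10⁻⁴).  Each labeled vector is then
replaced by its reconstruction

    x̂ = f(W⁽²⁾ f(W⁽¹⁾x + b⁽¹⁾) + b⁽²⁾),

and an RBF network (Gaussian kernels at k-means centers, ridge output
layer) or PLS-DA (NIPALS PLS2 on one-hot targets) classifies raw and
re-represented features alike.  Classifier hyperparameters are tuned by
quantum-behaved particle swarm optimization on cross-validated training
error.  See `docs/methods.md` for assumptions, defaults, and known
limitations — including a structural analysis of when the transfer step
can and cannot help.

## Worked example

```python
import json
import enose_stl as es

record = es.run_pipeline(n=3, classifier="rbf", seed=1)
record.pop("elapsed_s")
print(json.dumps(record, indent=2))
```

prints

```json
{
  "dim": 3,
  "classifier": "rbf",
  "hidden": 10,
  "unlabeled_size": 652,
  "seed": 1,
  "n_labeled": 80,
  "n_train": 60,
  "n_test": 20,
  "raw_train": 100.0,
  "raw_test": 100.0,
  "sae_train": 100.0,
  "sae_test": 100.0
}
```

One seed drives the whole run: 80 labeled curves (4 classes × 20) are
simulated and split 60/15-per-class train, 20 test; 652 unlabeled gas
curves train a 9–10–9 sparse autoencoder; both the raw normalized
features and their reconstructions are classified by a swarm-tuned RBF
network.  The four accuracy fields are percentages on the training and
test splits for each branch — at the default low noise the classes are
fully separable either way.  Raise `noise_sd` in `es.SimConfig` to probe
harder regimes, or use `es.run_grid(es.ExperimentGrid(...))` to sweep
dimension, pool size and hidden width.

The same stages are available from a shell:

```bash
enose-stl simulate --out curves/ --seed 3
enose-stl features --manifest curves/manifest.csv --n 3 --out features.csv
enose-stl train-sae --features features.csv --hidden 10 --out sae.json
enose-stl transfer --model sae.json --features features.csv --out recon.csv
enose-stl gradcheck --dim 4 --hidden 3
enose-stl experiment --dims 3,4,5 --repeats 5 --out grid.csv
```

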