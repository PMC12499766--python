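# grape-teb

Prediction of T-cell receptor (TCR) – epitope binding specificity by edge
classification on a bipartite interaction graph.

Recognition of peptide epitopes presented by MHC molecules is dominated by
the hypervariable CDR3β loop of the TCR β-chain. Public databases of
experimentally confirmed CDR3β–epitope pairs (VDJdb, McPAS-TCR, IEDB
curations) are small relative to the theoretical TCR diversity, extremely
sparse (interaction densities of order 10⁻³, mean node degrees near 1), and
severely imbalanced: a handful of immunodominant epitopes account for most
known binders. This package implements GRAPE, a graph-regularized attentive
model built for exactly this regime, for immunoinformaticians who want to
train and evaluate binding predictors on pair tables of
(CDR3β, epitope, label) rows.

## The model

Sequences are embedded by a pluggable provider (a deterministic hashed
k-mer provider ships for offline use; a protein-language-model provider
(ESM-2, 8M tier) is available when its checkpoint is installed). Unique
TCRs and epitopes become the two node sets of a bipartite graph
G = (V, E, X); every labeled pair is an edge, with a single edge type for
positive (y = 1) and negative (y = 0) pairs, so binding prediction is edge
classification.

The encoder stacks **graph-normalized convolution (GNCN)** layers. Each
layer transforms node features h_i = x_i W, rescales every row to a common
norm s, n_i = s·h_i/‖h_i‖, and propagates

    z_i = n_i/(d_i+1) + Σ_{j∈N(i)} n_j / (√(d_i+1)·√(d_j+1)),

equivalently s·D̂^{-1/2}ÂD̂^{-1/2} g(XW) with Â = A + I. The fixed-norm
rescaling keeps feature magnitudes from being averaged away in sparse
neighborhoods — the over-smoothing failure mode of vanilla graph
convolutions. A single **global attention** block,
Softmax(QKᵀ/√h)·V with Q = HW_Q, K = HW_K, V = HW_V, plus residual and
layer normalization, lets any node attend to any other. Pairs are scored
by an MLP on the pair representation together with a linear term on the
raw embedding interaction (see `docs/methods.md` for the scorer design).

Training addresses the class imbalance twice:

* **Dynamic negative sampling** — each epitope starts with a quota
  (default 10) of uniformly sampled non-interacting TCRs; after epochs
  where validation performance improves, a fraction M of the
  correctly-classified negatives is replaced with fresh unobserved pairs,
  while misclassified (hard) negatives are retained.
* **Deep AUC maximization** — the pairwise squared surrogate
  E[(1 − (f(x) − f(x')))²] of the AUC is optimized through its stochastic
  saddle-point form F(f, y; a, b, α) with descent on (model, a, b) and
  ascent on α, mixed with binary cross-entropy:
  L = τ·L_AUC + (1 − τ)·L_BCE (default τ = 0.5).

Cross-validation uses the **StrictTCR** discipline: unique TCRs (not rows)
are dealt into folds, so no TCR — and no sampled negative edge — ever
appears on both sides of a split.

## Worked example

A synthetic repertoire with planted binding structure (each epitope carries
a 3-mer motif; a TCR binds iff it contains that motif; 5% of labels are
flipped) exercises the full pipeline offline:

```bash
grape simulate --out pairs.csv --truth truth.json --tcr-universe tcrs.txt --seed 7
# wrote 500 records to pairs.csv
grape split pairs.csv --out folds.tsv --k 5 --seed 7 --extra-tcrs tcrs.txt
# assigned 500 TCRs to 5 folds
printf 'epochs: 100\npatience: 25\n' > train.yaml
grape train pairs.csv --out model.npz --folds folds.tsv \
      --candidate-tcrs tcrs.txt --config train.yaml --seed 7
# {"auc": 0.9504085657931812, "aupr": 0.8709142543131604, "best_epoch": 72}
grape predict model.npz pairs.csv --out preds.tsv
```

The reported numbers are validation metrics on the held-out StrictTCR
fold: AUC 0.950 means a randomly chosen true binder outranks a randomly
chosen non-binder 95% of the time among pairs whose TCRs were never seen
in training; AUPR 0.871 is the step-wise average precision, the more
demanding number under the ~1:2 validation imbalance here. `preds.tsv`
holds one calibrated-ish probability per input pair — the model is
trained primarily for ranking, so thresholds should be chosen on
validation data rather than read as absolute probabilities.

The same experiment through the API:

```python
from grape import SimConfig, TrainConfig, simulate_repertoire, strict_tcr_split, train

sim = simulate_repertoire(SimConfig(seed=7))
folds = strict_tcr_split(sim.records, k=5, seed=7, extra_tcrs=sim.tcr_universe)
checkpoint, metrics = train(sim.records, folds,
                            TrainConfig(epochs=100, patience=25, seed=7),
                            candidate_tcrs=sim.tcr_universe)
print(metrics.auc, metrics.aupr)
```

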