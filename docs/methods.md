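# Methods

## Problem and data model

The package predicts binary binding between a CDR3β sequence (the TCR
β-chain loop that dominates epitope contact) and a peptide epitope. The
atomic input is an `InteractionRecord` (tcr, epitope, label ∈ {0, 1});
sequences are validated against the strict 20-letter amino-acid alphabet
and invalid rows are dropped with a counted warning rather than failing
the whole table, since public exports routinely contain stray characters.
Duplicate pairs with conflicting labels resolve to the positive — an
experimentally confirmed interaction outweighs an assumed negative.

Dataset summaries report unique TCR and epitope counts, the number of
positive pairs, and the interaction density
n_pairs / (n_TCR × n_epitope) over positive pairs only. The public
benchmark tables reproduce, from their printed counts, densities of
0.0042 (McPAS), 0.0060 (TEINet), 0.0011 (VDJdb) and 0.0026 (recomputed
for the fourth dataset; its widely printed 0.0027 does not follow from
its own counts 31203/(28604×426) = 0.002561, so this package reports the
recomputed value).

## Graph construction

Unique TCRs and epitopes form the two node sets; features are embedding
rows; every labeled pair is an edge with a single edge type for both
labels, so the training adjacency propagates over positive and negative
edges alike (a positives-only adjacency is available behind
`BipartiteGraph.adjacency_mode` for ablation). Self-loops are not stored:
the GNCN's 1/(d_i+1) self term fixes the Â = A + I interpretation inside
the encoder. Node layout is deterministic — TCRs first, then epitopes,
each sorted — so runs are reproducible and serializations stable.

## Embeddings

Providers map sequences to fixed-width vectors behind one interface:

* `kmer_hash` (default, fully offline): sliding k-mer counts hashed into
  `width` bins by a seeded BLAKE2 hash, L2-normalized. Defaults k = 3,
  width = 320, hash seed 17. Width 320 matches the hidden size of the
  8M-parameter ESM-2 tier so the rest of the stack is provider-agnostic.
* `plm`: mean-pooled final-layer residue embeddings from ESM-2
  (checkpoint `esm2_t6_8M_UR50D`; the small tier is the default on the
  grounds that short CDR3β/epitope sequences do not benefit from larger
  capacity). The layer/pooling choice is configurable since no single
  convention is canonical; mean pooling is the default. When the optional
  dependency or checkpoint is absent the provider raises an explicit
  "external resource required" error — never a silent fallback.

## Encoder

Per-type input projections (separate 320→128 linear channels for TCR and
epitope nodes, ReLU) are followed by two GNCN layers. Each layer:
transform (H = XW, 128×128), normalize (every row rescaled to norm s),
propagate (symmetric degree-normalized adjacency with self term). s is
one learnable scalar per layer, parameterized through a softplus to stay
positive and initialized to 1. The zero-norm guard is ε = 1e-12. ReLU sits
between GNCN layers; the message form and the matrix form
s·D̂^{-1/2}ÂD̂^{-1/2}g(XW) agree to ~1e-15 (property-tested).

One global attention block (single head, width 128, scaled dot-product
over all nodes, residual + layer normalization) follows the GNCN stack.
The count, placement, and head multiplicity of attention are design
choices — one post-stack block keeps the attention-free configuration a
strict subnetwork, which the ablation switch exploits.

### Pair scorer (design choice)

The scorer is wide-and-deep. Deep path: an MLP (160 → 64 → 1) on the
concatenated pair representation [z_t ‖ z_e ‖ z_t ⊙ z_e]. Wide path: a
linear term w·(x_t ⊙ x_e) on the raw input embeddings, initialized at
zero. Two details matter and were chosen deliberately:

* **Why a product block and a wide term.** k-mer (and language-model)
  features carry pair evidence in *co-activated* dimensions — for the
  hashed provider, a TCR and an epitope sharing a 3-mer share a hash bin.
  An MLP on a bare concatenation must synthesize that conjunction from
  thresholded sums, and a dense 320→128 projection scrambles bin identity;
  in development this cost ~0.25 AUC on held-out TCRs relative to scorers
  with explicit multiplicative access. The elementwise product is the
  standard remedy in link prediction, and the raw-feature wide term keeps
  a direct, projection-free view of the interaction.
* **Tied initialization of the type channels.** The two per-type
  projections start from identical weights (they diverge freely during
  training). With independent random initializations the product block
  (W_t x_t) ⊙ (W_e x_e) has zero-mean entries and carries no signal at
  the start of training; with tied initialization it begins as a random
  sketch of the raw inner product.

Probabilities are produced by a logistic transform at the reporting layer
only; all losses except BCE act on raw logits.

The attention-free default configuration has 187 235 trainable parameters
(`count_trainable_parameters`), under the 200 000 bound the architecture
is designed to respect; enabling attention adds the three projection
matrices and layer-norm parameters.

## Losses and optimization

Empirical AUC is the Mann–Whitney rank statistic (ties count ½),
cross-checked in tests against brute-force pair enumeration and
scikit-learn. The pairwise squared surrogate
L_pair = mean over (pos, neg) pairs of (1 − (f(x) − f(x')))² is
decomposed into the per-sample saddle objective

    F = (1−p)(f−a)²·1[y=1] + p(f−b)²·1[y=−1]
        + 2(1+α)(p·f·1[y=−1] − (1−p)·f·1[y=1]) − p(1−p)α²

with p the positive-class prior. Minimizing mean F over (a, b) and
maximizing over α gives exactly p(1−p)(L_pair − 1), attained at
a* = mean(f | +), b* = mean(f | −), α* = b* − a*; the additive constant
p(1−p) does not move any optimum, so per-sample stochastic updates on F
optimize the pairwise objective. Both the identity and the stationary
point are asserted to 1e-6 in the test suite against the brute-force
oracle. α is unconstrained; the indicator masks are exact 0/1, no
smoothing.

The mixed loss is L = τ·L_AUC + (1−τ)·L_BCE with τ = 0.5 by default (the
model is insensitive over τ ∈ [0, 0.7]; τ = 1 removes the calibrating BCE
term and is not recommended). BCE uses the numerically stable
softplus(z) − z·y form. p is recomputed from the current training edge
set after every dynamic-sampling update.

One simultaneous update per edge mini-batch: Adam (lr 1e-3) on model
parameters, plain gradient descent (lr 1e-2) on (a, b), ascent (same lr)
on α. Non-finite gradients reject the step with a diagnostic. A norm
bound on the scorer weights can be enabled as uniform weight decay
(`LossConfig.weight_decay`, off by default).

Regularization defaults: dropout 0.5 on the pair-head activations
(training only — encoding is deterministic given parameters) and Adam
weight decay 1e-2 on encoder and head weight matrices, with biases,
layer-norm parameters and the wide term exempt. At desk scale the deep
path can otherwise memorize a few hundred training edges outright.

Gradients come from a minimal reverse-mode autodiff engine over float64
numpy arrays (`grape._autograd`); every primitive's vector-Jacobian
product is checked against central finite differences in the test suite.

## Negative sampling

Initial negatives: per epitope, a quota (default 10) of TCRs drawn
uniformly without replacement from candidates not positively paired with
it; shortfalls are taken in full and logged. Dynamic update, once per
epoch: negatives with predicted probability ≥ 0.5 (misclassified) are
retained; floor(M × n_correct) of the rest are replaced by fresh draws
from the same epitope's pool (quota-preserving), avoiding positives and
current negatives. Resampling is gated on validation improvement: when
the best validation AUC so far is not surpassed, the set is frozen for
the next epoch (a flag disables gating). M defaults to 0.1, inside the
0.01–0.3 range where behavior is flat. Setting M = 0 reduces the whole
run to static negative sampling.

## Training, evaluation, leakage control

Folds are StrictTCR: unique TCRs are sorted, permuted under the seed, and
dealt round-robin, so the assignment is row-order invariant and fold sizes
differ by at most one. The fold deal may include extra TCR sequences
(repertoire members without observed interactions) so that per-fold
negative-sampling pools are disjoint by construction; training asserts at
runtime that train/validation TCR sets and negative-edge sets are
disjoint.

Validation pairs are scored transductively: held-out nodes sit in the
graph but their edges never enter the message-passing adjacency, and
embeddings are computed from train edges only. Validation negatives are
drawn from validation-fold TCRs with the same per-epitope quota. The best
checkpoint by validation AUC is returned (patience 10 by default; the
bundled experiments extend it to 25 because the desk-scale validation AUC
trace is noisy). AUPR is step-wise average precision — the conservative
convention under imbalance. Batch construction is edge mini-batches with
a full-graph encode per step, which is cheap at the scales this package
targets.

Ablation switches mirror the model's components: no attention, no dynamic
sampling (M = 0), no AUC loss (τ = 0), no graph normalization (g(·)
replaced by identity); all four off yields a plain graph-convolutional
baseline with BCE and static negatives.

## Synthetic repertoire

The generator plants an exactly recoverable rule: each epitope gets a
distinct random motif (length 3 = default k-mer size), implanted in the
epitope's own sequence; a TCR binds an epitope iff it contains that
motif. True pairs are subsampled to a target density, motifs are
implanted into TCRs when random containment falls short of the target,
and emitted labels flip independently with probability ε (default 0.05).
CDR3β sequences use the C…F flanking convention for cosmetic realism
only.

Default dimensions are 500 TCRs × 20 epitopes at density 0.05, i.e. mean
TCR degree 1.0 — the sparse regime of the public datasets, whose
10⁻³-scale densities arise from having hundreds to thousands of epitopes
at the same per-TCR degree, not from fewer interactions per TCR. The
densities of the real tables are reproduced in summary-statistics
fixtures (`records_from_counts`) rather than by the generator's default
geometry.

What the generator does **not** emulate: V(D)J recombination statistics,
germline-biased sequence composition, epitope immunodominance hierarchies,
cross-reactive motifs shared between epitopes, and assay-specific label
noise structure. Passing the recovery experiment therefore demonstrates
that the pipeline is implemented coherently and can extract a planted,
k-mer-decodable signal under realistic sparsity and leakage control — not
that it attains any particular accuracy on real repertoires.

## Bundled experiments

* **Recovery** (`experiments.recovery_experiment`): full pipeline on the
  default repertoire, 5 seeds, 100 epochs; the median validation AUC is
  the headline number (≈ 0.94–0.96 in practice).
* **Imbalance** (`experiments.imbalance_experiment`): the sparse regime
  (density 0.004, ~40 positives) with per-epitope quota 80 gives a ≈ 1:50
  positive:negative training ratio; τ = 0.5 is compared against τ = 0
  over 10 seeds. The comparison is directional: the mixed loss should not
  be worse, and is typically a few AUC points better.

Problem sizes were chosen so the whole experiment battery completes in
minutes on one CPU; they are stated in the function signatures and echoed
in the acceptance output.

## Known limitations

* Scores are optimized for ranking; probability calibration is weak,
  particularly under heavy weight decay — threshold on validation data.
* Full dense attention is O(n²) in node count; fine at desk scale,
  unsuitable beyond ~10⁴ nodes without an approximation.
* Transductive scoring handles unseen sequences as isolated nodes; a
  sequence dissimilar to anything in training is scored almost entirely
  by the wide term on its raw embedding.
* The checkpoint stores the training edge list to rebuild the adjacency;
  it is not a portable serialization format across package versions.
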