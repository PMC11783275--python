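# Methods

## The prediction problem

A single- or multi-point amino-acid substitution changes a protein's
folding free energy by ΔΔG (kcal/mol); under the sign convention used
throughout this package, negative ΔΔG means the variant is destabilizing.
`embddg` predicts ΔΔG from sequence alone, in two steps: a per-residue
embedding difference encodes the variation, and a small convolution +
transformer-encoder head regresses the scalar.

## Input encoding

Both the wild-type and the variant sequence (same length L — only
substitutions are supported, never indels) are embedded into L×d matrices
E_wt and E_vt by a per-residue sequence embedder; the model input is the
difference

    D = E_wt − E_vt.

D is exactly antisymmetric under exchanging the two sequences, so a
variation and its reverse are encoded by D and −D. Because embeddings are
contextual, a substitution perturbs rows beyond the varied position, and D
is a localized but not single-row pattern.

Two embedders implement the contract:

* **ESM2 adapter** (`ESM2Embedder`) — the pretrained 33-layer, 650M
  parameter ESM2 model, d = 1280. Per-residue representations are taken
  from a configurable layer (default: the final one; which layer is best is
  an open choice) and the begin/end special tokens are stripped so rows
  align 1:1 with residues. Sequences longer than the model context
  (default cap 1022 residues) are rejected rather than silently truncated.
  Requires the optional `torch`/`fair-esm` dependencies.
* **Mock embedder** (`MockEmbedder`) — a deterministic k-mer-contextual
  stand-in used by the test-suite and synthetic experiments: row j is a
  seeded pseudo-random function (hash of the k-mer centred at j,
  boundary-padded), so a point substitution perturbs exactly the rows
  within (k−1)/2 of the site. Defaults d = 32, k = 7. A per-residue
  (k = 1) mock would make D nonzero only at varied positions and
  under-exercise the downstream model; the windowed construction keeps the
  essential contextual property at desk scale.

Embeddings can be cached in an HDF5 file keyed by embedder name and a SHA1
hash of the residue string (ids are not unique across files; the id is
kept as an attribute). Cached matrices are bit-identical to fresh ones for
deterministic embedders.

## The regression head

Given D (L×d), with hyperparameters m (filters), w (filter width), h
(heads), r = m/h, s (FFN hidden size):

1. **1D convolution**, m filters of width w over the d input channels,
   zero same-padding (output keeps L rows), ReLU: C (L×m). Padding choice
   is forced by the residual connection and pooling below, which need
   length preservation.
2. **One transformer-encoder layer**:
   - per head i: Q_i = C·A^Q_i, K_i = C·A^K_i, V_i = C·A^V_i (each A is
     m×r); Z_i = softmax(Q_i·K_iᵀ/√r)·V_i;
   - heads concatenated, projected and added residually:
     Z = [Z_1 … Z_h]·A^O + C;
   - position-wise FFN with residual:
     f_j = ReLU(z_j·W1 + b1)·W2 + b2 + z_j.
   There is **no positional encoding, no layer normalization, no
   dropout** — the encoder is exactly these equations (an optional layer
   norm exists behind a non-default flag, and plain 1/r attention scaling
   behind another, for sensitivity checks; √r is the conventional scaled
   dot-product definition and the default).
3. **Pooling and read-out**: global average and max pooling over the L
   rows of F give p_ave and p_max (m each); ŷ = [p_ave, p_max]·w_O + b_O.

Because nothing injects position information after the convolution, the
post-conv pipeline is permutation-invariant in the rows of C; the test
suite asserts this, along with row-stochastic attention and exact
equivalence of every stage with naive scalar-loop oracles.

Named presets span the explored grid: model0 (m=32, h=2, s=128) …
model5 (256, 8, 1024); model4 (m=128, h=8, s=512, hence r=16) is the
production configuration. All presets use w = 15.

### Batching and masking

Variable-length inputs are zero-padded to a common L and masked. Padded
rows are zero, so the convolution sees them exactly as its own zero
padding; padded keys get zero attention weight (the softmax is computed
only over valid keys — no −∞ arithmetic, and shifted scores are clamped at
−700 to stay off the subnormal path); pooling runs over valid rows only.
Batched predictions therefore equal single-sequence predictions to
floating-point exactness, which the suite asserts.

### Numerics

Everything is float64 NumPy. Softmax uses max-subtraction, so outputs are
finite for any finite input. Max-pooling returns values, not indices, so
ties need no tie-break in the forward pass; in the backward pass the
gradient is routed to the first maximal row (ties have measure zero for
continuous inputs). Gradients of all stages are hand-derived reverse-mode
and verified against central finite differences at 1e−5 tolerance.

## Training

Mean squared error, minimized with Adam (β₁ = 0.9, β₂ = 0.999) on
minibatches of 128 for up to 500 epochs. Early stopping: a validation
subset — 10% of training *proteins*, grouped so no protein straddles the
split, selected by the run seed — is monitored each epoch and the
parameters from the epoch with minimum validation MSE are returned, with a
patience of 20 non-improving epochs (all configurable). The learning rate
defaults to 1e−4; an optional reduce-on-plateau schedule multiplies it by
`lr_decay_factor` after every `lr_decay_patience` non-improving epochs.
Optional decoupled (AdamW-style) weight decay acts on weight matrices,
never biases; it defaults to 0.

**Reversibility augmentation.** Thermodynamic reversibility,
ΔΔG(A→B) = −ΔΔG(B→A), doubles a direct-variation dataset: each record
contributes a reverse record whose wild type is the mutated sequence,
whose substitutions are inverted, and whose target is negated. Because the
encoding satisfies D(rev) = −D(direct) exactly, augmentation both balances
the destabilizing bias of curated datasets and supervises antisymmetry.
Augmenting an already-augmented set is rejected.

## Homology-aware cross-validation

Pairwise sequence identity is computed from a global (Needleman–Wunsch)
alignment with match +1, mismatch 0, gap open −2, gap extension −0.5;
identity = identical aligned pairs / alignment length (gaps included).
These scores are a documented package choice — the identity threshold, not
the scoring, is the protocol's active ingredient.

Folds are built so that no information leaks across them: proteins are
clustered by single linkage at >25% identity (transitive closure, so
A~B~C chains into one cluster even if A and C are dissimilar); clusters
are atomic and are dealt greedily — largest total variation count first,
onto the lightest fold — to balance fold sizes; ties among equal-count
clusters are broken by the seed. The no-leak constraint is re-checked
exhaustively after assignment. All variations of a protein stay together
by construction. Cross-validation trains on the remaining folds (with
reverse augmentation) and scores the held-out fold; the summary reports
mean ± SD over folds of the Total-block PCC/RMSE/MAE.

## Scoring

Five indices, reported for Total (direct + reverse), Direct, and Reverse
partitions: Pearson correlation (PCC), RMSE, MAE; plus two antisymmetry
statistics over paired direct/reverse predictions: r_d−r (Pearson between
direct and reverse predictions; −1 for a perfect antisymmetric predictor)
and the bias δ = Σ(p_dir + p_inv)/(2N), zero iff the predictor is
antisymmetric on the evaluated pairs and signed, so systematic shifts keep
their direction. Experimental reverse targets are the negated direct
values. Correlations on zero-variance inputs are reported as missing,
never coerced to zero.

## Synthetic tasks

`make_task` emulates the shape of curated stability datasets without any
download: n_proteins random sequences (default 20, lengths 60–120),
n_variants labeled variations (default 500, 10% multi-point with 2–5
sites), targets

    y = c · mean_j(D_j) · u + ε,   ε ~ N(0, σ²),

with u a fixed random functional and c set so the noise-free targets have
SD 1.5 kcal/mol (a realistic spread for stability compilations); σ
defaults to 0.15 kcal/mol, i.e. 10% of the signal SD, on the order of
experimental measurement error. Linearity in D makes the noise-free
ground truth exactly antisymmetric and guarantees the target is inside
the model class, so recovery experiments are sharp. What the generator
does **not** emulate: real thermodynamics, heavy-tailed experimental ΔΔG
distributions, or the manifold structure of real language-model
embeddings — mock embedding rows are i.i.d. random vectors, which makes
memorization *easier* and generalization *harder* than on real data, so
passing the recovery check is a conservative signal about the training
loop, not a claim about real-data accuracy.

`make_dissimilar_families` generates families by point-mutating a random
ancestor at 30% of positions (within-family identity ≈ 70% ≫ 25%)
against independent random ancestors (between-family identity at the
~5–15% alignment background), exercising the fold protocol's clustering
and leak check.

### The recovery experiment

The standing end-to-end check trains the smallest preset (model0) with
reverse augmentation on 15 of a 20-protein task (500 variants, σ = 0.1·SD)
and scores the 5 held-out proteins on PCC and the antisymmetry bias
(bars: held-out PCC ≥ 0.9, |δ| ≤ 0.1·SD of the held-out targets).

Because mock-embedding rows are unstructured random features, the head at
standard initialization interpolates the training set within ~10 epochs
while held-out error stalls — the classic random-feature memorization
regime (a linear probe on mean-pooled D generalizes to the noise floor,
so the signal itself is recoverable). The recovery configuration
(`embddg.synthetic.recovery_train_config`) therefore starts from weights
at 0.3× the standard He/Glorot scale and applies decoupled weight decay
0.15 with lr 3e−3, batch 128, ≤100 epochs, patience 40: small
initialization keeps the optimization on low-norm trajectories where the
pooled linear signal dominates, and the decay keeps memorizing directions
suppressed. Under this configuration held-out validation error
approaches the noise floor within a few dozen epochs. Real pLM
embeddings live on a much lower-dimensional manifold than the i.i.d.
mock rows, so this failure mode overstates what full-scale training
encounters; the default `TrainConfig` consequently leaves weight decay
off and initialization at standard scale.

## Problem sizes

Test-suite and acceptance runs use desk-scale instances chosen as the
package's own defaults: oracle comparisons at L ≤ 6, m ≤ 8; recovery at
20 proteins / 500 variants with d = 32 mock embeddings; fold fixtures of
8 families × 3 members. These sizes exercise every code path; they are
not the sizes a production training run would use (full-scale training
with the ESM2 embedder at d = 1280 uses the same code via the CLI).

## Known limitations

* Only substitutions are modeled; indels change L and are rejected.
* The ESM2 adapter is exercised only through its error path in
  environments without the optional heavy dependencies.
* Which ESM2 layer to extract, and how the authors of the architecture
  handled very long sequences, are genuinely open; both are configuration.
* The training loop is single-process CPU NumPy; it is intended for
  method study and desk-scale experiments, not large-scale pretraining.
* δ is reported signed; its absolute value should be used when ranking
  methods by antisymmetry alone.
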