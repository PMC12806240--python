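# Methods

## Model overview

peakcast annotates single-cell chromatin accessibility (scCAS) profiles by
label transfer in a learned embedding space. The pipeline assumes a shared
peak space between training, reference and test data (exact
`chrom:start-end` matching, BED half-open convention; no interval-overlap
remapping), non-negative integer counts, and a training set with at least
two labelled cell types, each with at least one cell.

### Preprocessing

Peaks with at least one read in at least `min_cell_fraction` (default 0.03)
of training cells are kept; the comparison is against the exact real-valued
cutoff `0.03·N`, without rounding. Only the selected indices travel to the
reference and test sets.

TF-IDF treats cells as documents and peaks as terms:
`x'_ij = (x_ij/Σ_i x_ij) · ln(n/Σ_j x_ij)`, then each cell is L2-normalized.
Two deliberate readings of this formula are worth flagging:

* the IDF uses **raw row sums**, not binarized document frequency. A peak
  whose total count exceeds the number of cells gets a negative weight; we
  keep the formula as printed rather than clipping. A consequence is that
  globally rescaling a count matrix is *not* a no-op: the scale passes
  through the IDF argument as a per-row `−ln c` shift (the term-frequency
  part cancels it). The tests assert exactly this behaviour.
* each dataset is normalized with **its own** statistics (`n` and row sums
  of the matrix at hand); the selected peak indices are the only state
  carried over. `idf_from_train=True` freezes training IDF weights instead,
  as an ablation.

Zero totals are guarded: all-zero cells stay all-zero, zero-count peaks
contribute nothing.

### Prior-seeded architecture

The encoder is a two-layer perceptron: input `p'` → hidden layer →
rectifier → linear output (default 64 dimensions). The hidden layer is
partitioned into blocks:

* **random** — 128 units, uniform fan-based initialization;
* **pca_train** — 100 units initialized with PCA components of a bootstrap
  prior: for each of 1000 replicates and each type, 500 same-type cells are
  drawn with replacement and averaged into a pseudo-cell (drawing counts
  come from a multinomial, which is equivalent and vectorizes); the pooled
  sample stacks one pseudo-cell per type per replicate (K×1000 columns).
  The alternative pooling — averaging the K pseudo-cells within each
  replicate — is available (`prior_pooling="per_replicate"`) but collapses
  type structure, which would make a K-type prior invisible to PCA;
* **pca_reference** — 100 more units when a reference matrix is supplied,
  carrying PCA components of the aligned, TF-IDF-normalized reference
  (no bootstrap). Hidden width is therefore 228 without and 328 with a
  reference.

The bootstrap operates on the TF-IDF matrix, not raw counts, because the
PCA weights must live in the space the encoder consumes. PCA centering is
absorbed into unit biases (`b = −mean·components`), so before any gradient
step each PCA unit outputs exactly the centered PCA score of its input —
this identity is tested to 1e-8. All blocks stay trainable; the PCA blocks
are an initialization, not a frozen projection. If a requested component
count exceeds the feasible rank, it is truncated with a warning.

### Contrastive objective

Training pairs are two independent draws of one uniformly random cell per
type (a type with a single cell pairs with itself, logged as a warning).
For per-type embeddings `Za, Zb` (K×d):

    loss = −log [ Σ_i exp(sim(z_a_i, z_b_i)/τ) / Σ_{i≠j} exp(sim(z_a_i, z_b_j)/τ) ]

with cosine similarity (norms guarded by ε = 1e-8) and temperature τ
(default 0.5). Two properties distinguish this from standard InfoNCE and
are implemented verbatim: all K positives are aggregated inside a single
log, and the denominator contains only cross-type terms, so the ratio can
exceed one and the loss can be negative. At K = 2 with orthogonal types and
coincident positives the loss is exactly −1; with all embeddings identical
it is `ln(K−1)` (zero only at K = 2).

Optimization: one pass over 10,000 pairs in mini-batches of 64, batch-mean
loss, Adam at learning rate 1e-3. The free design choices here (depth,
output dimension 64, optimizer, batch size, τ) are exposed as parameters.
The network, its backward pass and Adam are written directly in NumPy: the
model is small (a few hundred hidden units), runs in seconds on one CPU
thread, analytic gradients are verified against central finite differences
to 1e-5 relative error, and fixed seeds give bit-identical weights.

### Label transfer and open-set detection

A test cell's profile is its mean cosine similarity to the training cells
of each type (computed as a dot product with the mean of the type's unit
vectors, which is algebraically the mean of cosines); the argmax wins, ties
break alphabetically and are logged.

Uncertainty is the Shannon entropy of `softmax(s̄/τ)`. Using the model's
contrastive temperature as the softmax scale is deliberate: the training
loss already treats `sim/τ` as logits, so this is the model's own
probabilistic reading of a similarity profile rather than a new tuning
knob. `PredictionResult.entropy` stores the value normalized by `ln K`
(bounded [0, 1]).

Novel-type flagging is cluster-level: Leiden clustering of the test set
(PCA of the normalized test matrix, up to 100 components; k-nearest-neighbor
graph with k = 15; resolution found by bisection on [1e-3, 50], at most 40
iterations, targeting `round(1.5 · K)` clusters, accepting the closest
attainable count otherwise), then every cell in a cluster whose mean
entropy strictly exceeds 0.7 **nats** is re-labelled `novel`.

The nats scale is a considered choice. K mutually separated unit vectors
can be pairwise at cosine at most −1/(K−1), which bounds the entropy of a
perfectly confident profile from below; at K = 4 that floor is ≈ 0.65 nats
under the τ-scaled softmax but ≈ 0.85 on the ln K-normalized scale — above
the 0.7 cutoff, which would flag every cluster regardless of training
quality. In absolute information units the fixed 0.7 threshold separates
confident clusters (just above the geometric floor) from unmatched ones.
`flag_novel(..., scale="normalized")` applies the threshold on the [0, 1]
scale instead.

### Metrics

macro-F1, Cohen's kappa, macro-averaged per-class Jaccard and accuracy are
computed via scikit-learn behind a thin surface that fixes the conventions:
macro averages run over classes observed in the true labels, empty classes
score 0 (0/0 → 0), and two constant, equal label vectors get kappa 1 by
convention. The literal set-form Jaccard `|A∩B|/|A∪B|` over label-name sets
is degenerate for multi-class vectors (the sets usually coincide) and is
kept only behind `literal_sets=True`. The imbalance degree
`I = 1 + (1/log K) Σ (N_k/N) log(N_k/N)` is 0 for balanced types, 1 for a
single type (defined as 1 at K = 1), and invariant to the log base and to
scaling all counts.

## Synthetic data

The generator emulates the structure of real scCAS matrices: each type owns
a contiguous block of `peaks_per_type` signature peaks, accessible at rate
`q1` (default 0.2) against a background rate `q0` (default 0.005), Bernoulli
counts by default (a Poisson option exists). Adjacent blocks overlap by
`shared_fraction`, making signature overlap a single monotone difficulty
knob. Defaults (5 types × 200 cells, 5000 peaks, 100-peak signatures)
produce ~99% sparsity, matching the regime of published scATAC-seq
collections. Dropout thinning (zeroing nonzero entries with fixed
probability) emulates reduced coverage; cells split 50/50 into train/test
stratified by type, and withheld types are removed from training only.

What it does **not** emulate: batch effects, co-accessibility structure,
fragment-level counts, shared housekeeping accessibility, or peak-calling
noise. Passing the synthetic benchmarks therefore demonstrates that the
pipeline's machinery is correct and that its behaviour degrades sensibly
with noise and imbalance — not that real-data accuracy will match these
numbers. One notable artefact of the disjoint-signature regime: a withheld
type's cells retain almost no selected features, so they embed as faint
mixtures of known signatures rather than as a distinct mass; novel-type
detection at the fixed 0.7-nat threshold still separates them, but with a
thinner margin than cleanly distinct real cell types would give.

## Problem sizes and numerical choices

The test-suite and acceptance benchmarks run at 5 types × 200 cells × 5000
peaks (scaled-down but structurally faithful study conditions), with 5-fold
cross-validation and medians over small seed sets; a full fit takes a few
seconds on one CPU. Tolerances: oracle equivalences at 1e-10, linear-algebra
identities at 1e-8, gradient checks at 1e-5 relative. Degenerate inputs are
defined, not special-cased downstream: 0/0 → 0 throughout preprocessing,
ε-guarded norms in cosine similarity, empty peak selections and empty label
classes are hard errors, and Leiden bisection logs when the exact cluster
count is unattainable.

## Known limitations

* Exact peak-string matching only; references on a different peak
  annotation must be re-quantified upstream.
* Novel-type detection assigns a single reserved label; it does not
  subdivide or name multiple novel populations.
* The entropy threshold is calibrated in absolute nats; for very large K
  (≫ 20) a uniform profile has entropy ≫ 0.7 nats and flagging becomes
  more liberal.
* No batch correction; strong batch structure between training and test
  will inflate novel flags.
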