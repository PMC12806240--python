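# peakcast

Reference-guided cell-type annotation for single-cell chromatin
accessibility (scATAC-seq / scCAS) data.

## The problem

scCAS experiments produce peak-by-cell count matrices that are near-binary
and extremely sparse (typically ~99% zeros). Annotating each cell with a
cell type is the first step of almost every downstream analysis, and doing
it automatically requires transferring labels from an annotated training
set to new cells — ideally while (i) exploiting any unlabelled reference
atlas that shares the peak space, and (ii) recognising cells whose type was
never seen in training instead of silently mislabelling them.

## The method

Given a peak-by-cell count matrix `X ∈ R^{p×N}` with cell-type labels:

1. **Peak selection** keeps peaks with at least one read in ≥ 3% of
   training cells; the selected indices are reused verbatim for reference
   and test data.
2. **TF-IDF normalization** (cells as documents, peaks as terms):
   `x'_ij = (x_ij / Σ_i x_ij) · ln(n / Σ_j x_ij)`, followed by per-cell L2
   normalization `v_ij = x'_ij / √(Σ_i x'²_ij)`.
3. **Prior-seeded encoder.** A two-layer MLP embeds cells. Its hidden layer
   is structurally partitioned: 128 randomly initialized units plus 100
   units whose incoming weights are the top-100 PCA components of a
   bootstrap prior (1000 replicates of averaging 500 same-type cells drawn
   with replacement). With an external reference matrix, a further 100
   units carry the reference's PCA components (hidden width 228 → 328).
   Biases absorb PCA centering, so each PCA unit initially outputs exactly
   the corresponding PCA score. All weights remain trainable.
4. **Contrastive training.** 10,000 training pairs are built by twice
   drawing one random cell per type; aligned positions are positives,
   cross-type combinations negatives. For per-type embeddings `Za, Zb`
   (K×d) the loss is

   `loss = −log [ Σ_i exp(sim(z_a_i, z_b_i)/τ) / Σ_{i≠j} exp(sim(z_a_i, z_b_j)/τ) ]`

   with cosine similarity `sim` and temperature `τ = 0.5`, minimized with
   Adam. The network is implemented directly in NumPy (forward, backward
   and optimizer), which keeps runs bit-reproducible for a fixed seed.
5. **Label transfer.** A test cell receives the training type with the
   highest mean cosine similarity in embedding space.
6. **Novel-type detection (optional).** Per-cell uncertainty is the Shannon
   entropy of `softmax(s̄/τ)` over the per-type mean similarities. The test
   set is Leiden-clustered (on PCA of the normalized matrix, targeting
   `⌈1.5·K⌋` clusters via resolution bisection) and every cell in a cluster
   whose mean entropy exceeds 0.7 nats is re-labelled `novel`.

Evaluation helpers implement macro-F1, Cohen's kappa, macro Jaccard,
accuracy, and the dataset descriptors sparsity and imbalance degree
`I = 1 + (1/log K) Σ_k (N_k/N) log(N_k/N)`.

## Worked example

```python
from peakcast import SimConfig, simulate_dataset, ContrastiveAnnotator
from peakcast.metrics import compute_report, describe_dataset

cfg = SimConfig(seed=1)               # 5 types x 200 cells, 5000 peaks
train, test, truth = simulate_dataset(cfg)
desc = describe_dataset(train)
print(f"sparsity={desc.sparsity:.3f}  imbalance={desc.imbalance_degree:.3f}")

est = ContrastiveAnnotator(random_state=1).fit(train.counts.T, train.labels)
print(f"hidden width: {est.hidden_width_}")
report = compute_report(test.labels, est.predict(test.counts.T).tolist())
print(f"accuracy={report.accuracy:.3f}  macro-F1={report.macro_f1:.3f}  "
      f"kappa={report.kappa:.3f}  Jaccard={report.jaccard:.3f}")
```

Output:

```
sparsity=0.991  imbalance=-0.000
hidden width: 228
accuracy=1.000  macro-F1=1.000  kappa=1.000  Jaccard=1.000
```

The simulated matrix matches the sparsity regime of real scATAC-seq
collections (99.1% zeros, balanced types). The hidden width 228 reflects
the 128 random + 100 PCA-initialized units (no reference supplied). On
this well-separated benchmark the annotator recovers every held-out test
cell's type, so all four agreement metrics are 1.

`ContrastiveAnnotator` follows scikit-learn conventions (`fit`, `predict`,
`predict_open`, `transform`, `get_params`), so it composes with sklearn
model selection. The same pipeline is available from the shell:

```sh
peakcast simulate --out data/
peakcast train   --matrix data/train.mtx --peaks data/train_peaks.bed \
                 --labels data/train_labels.tsv --out ckpt/
peakcast predict --checkpoint ckpt/ --matrix data/test.mtx \
                 --peaks data/test_peaks.bed --detect-novel --out pred.tsv
peakcast evaluate --pred pred.tsv --truth data/test_labels.tsv --out metrics.json
```

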