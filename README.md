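# exprgat

Graph-attention embeddings of expression samples for phenotype
prediction, patient stratification and cell clustering.

## The problem

Bulk and single-cell RNA-seq cohorts carry strong sample–sample
structure: patients of the same cancer subtype, or cells of the same
tumor, have correlated expression profiles.  Most classifiers and
clustering methods ignore that structure; graph neural networks use it
but weight all neighbors equally.  `exprgat` embeds each sample by
*attending* over its most-correlated neighbors, learning per-neighbor
weights end to end, so that the neighbors that actually matter for the
downstream task dominate the embedding.

## The model

Given a feature matrix `X ∈ R^{n×m}` (samples × genes, optionally
log2(x+1)-transformed and PCA-reduced), a binary adjacency `A` keeps
each sample's top-k Pearson-correlated neighbors (k set by a target
network density) plus a self-connection.  One attention head with
projection `W ∈ R^{p×m}` and attention vector `a ∈ R^{2p}` scores each
neighbor pair

    c_ij = aᵀ [W x_i ‖ W x_j]

passes the scores through LeakyReLU, masks them to the graph support
and softmax-normalizes per row into coefficients `α_ij`; the head's
output is `σ(Σ_{j∈N_i} α_ij W x_j)`.  `h` independent heads are
concatenated into the embedding `Z ∈ R^{n×ph}`, which feeds either

* **a classifier** — one fully connected layer + softmax, trained
  transductively with negative log-likelihood under an 80/20
  pre-train/test, 80/20 train/validation split protocol; or
* **a clustering autoencoder** — a four-layer decoder (widths
  `ph/2, m/4, m/2, m`) trained by mean-squared reconstruction error,
  followed by agglomerative clustering of the encoder's embeddings.

Post hoc, an **attention matrix** `M_ij = max_k α^k_ij` summarizes
which neighbors the trained model found important; its rows can be
clustered in place of the adjacency.

Everything, including backpropagation through the masked attention
layer, is implemented in numpy; PCA and agglomerative clustering use
scikit-learn.

## Worked example

```bash
python examples/stratify_patients.py
```

simulates a 250-sample cohort with five planted subtypes, trains the
autoencoder and clusters the embeddings:

```
cohort: 250 samples, 5 planted subtypes
autoencoder reconstruction MSE: 13.554 -> 1.446 over 500 epochs
clustering vs planted subtypes: NMI=1.000, ARI=1.000
```

The reconstruction loss dropping ~10× shows the encoder compresses the
data through the graph-attention bottleneck; NMI/ARI of 1.0 mean the
hierarchical clustering of the embeddings recovers the planted
subtypes exactly.  `examples/classify_phenotype.py` runs the
supervised pipeline (test AUROC 1.000 on a separable imbalanced task),
`examples/attention_matrix.py` inspects the trained attention matrix,
and `examples/cli_workflow.sh` chains the CLI subcommands
(`simulate`, `preprocess`, `build-graph`, `train-classifier`,
`embed-cluster`, `extract-attention`).

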