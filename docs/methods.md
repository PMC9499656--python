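# Methods

## Model

`exprgat` treats an expression cohort as a graph whose nodes are
samples (patients or cells).  The modelling assumption is
assortativity: samples with similar expression profiles tend to share
the phenotype or subtype of interest, so information from correlated
neighbors should sharpen a sample's representation — but not all
neighbors equally, which is what the learned attention supplies.

**Graph.**  Pearson correlation between sample rows defines
similarity; per sample, the `k = max(1, round(density·(n−1)))` most
correlated other samples become its neighborhood, and a
self-connection is always added (never counted toward `k`).  The
result is binary and in general directed: row `i`'s nonzeros are
exactly the set the attention softmax of sample `i` normalizes over,
which is why no symmetrization is imposed.  Ties at the k-th rank keep
the lower sample index, making graph construction deterministic.
Pearson is used because it is the standard similarity for expression
profiles and is invariant to positive affine rescaling of a sample.

**Attention layer.**  Head `k` projects samples with `W ∈ R^{p×m}` and
scores ordered pairs with `a ∈ R^{2p}` as `c_ij = aᵀ[Wx_i ‖ Wx_j]`,
computed in decomposed form `s_i + t_j` (rank-one structure) rather
than materializing concatenated pairs.  Scores pass through LeakyReLU
(negative slope 0.2, the original graph-attention convention — the
slope is configurable), are masked by setting non-neighbor entries to
−∞ *before* the softmax (this preserves exact row normalization; the
masked entries come out identically zero), and the head output is
`ELU(α · XWᵀ)`.  ELU is the default nonlinearity, again following
graph-attention convention since the choice is otherwise open;
`relu` and `identity` are selectable.  Heads are initialized
Xavier-normal (`W`: variance `2/(m+p)`; `a`: variance `2/(2p+1)`) from
an explicit seed, and the `h` head outputs are concatenated.

Only a single attention layer is used: one layer feeds the downstream
heads directly, and the neighborhoods are already global in the sense
that they come from whole-profile correlation.

**Classifier.**  A single fully connected layer + softmax maps `Z` to
class probabilities; training minimizes the negative log-likelihood of
the training subset.  The regime is transductive: all samples and the
whole graph participate in every forward pass, only training labels
enter the loss.  Splits follow an 80/20 pre-train/test division with
the pre-train set split 80/20 into train/validation; splitting is
stratified by default (largest-remainder allocation per class, so the
global sizes are exactly `round(0.2·n)` and `round(0.2·|pretrain|)`),
and the checkpoint with the best validation loss is returned.
Optimizer: Adam, learning rate 0.005, weight decay 5e-4, at most 500
epochs with early stopping at patience 50 — standard graph-attention
training settings; all are config-exposed.

**Clustering autoencoder.**  The attention layer is the encoder; the
decoder is four fully connected layers of widths `ph/2, m/4, m/2, m`
(floor division, floored at width 1), ReLU after the first three,
linear output.  The loss is the mean squared error between input
features and reconstruction.  As a sum of squared row norms its
minimizer is identical; the mean over all `n·m` entries is used so the
loss scale — and hence a single default learning rate (Adam, 0.001) —
transfers across data sizes.  Training is fully unsupervised: no
splits, no early stopping (there is no validation target), 500 epochs
by default.  Embeddings from the trained encoder are clustered
agglomeratively (scikit-learn); presets mirror the two data regimes:
`blca` (bulk patient stratification) = Manhattan distance + average
linkage, `scrna` (cell clustering) = cosine + average.  Ward linkage
is restricted to Euclidean distance.  `k` is always user-supplied,
never estimated.

**Attention matrix.**  For interpretation, per-head coefficients are
recomputed on the trained parameters and reduced by elementwise max
over heads, yielding `M` with `M_ij ∈ [0,1]`, zero exactly off the
graph support, rows not necessarily summing to one.  Rows of `M`
serve directly as feature vectors for clustering.  Unlike the
embedding presets, the default metric here is **cosine**: the max
reduction gives rows unequal total mass, and the group signal lies in
*which* neighbors a sample attends to rather than in that scale.  On
planted-cluster data, Manhattan distance on raw attention rows mixed
scale with support and degraded recovery (NMI 0.69) even though
within-group attention strictly dominated between-group attention;
cosine (or row-normalized Manhattan) recovered the planted groups
exactly.  When attention clustering is compared against
adjacency-matrix clustering, the same metric is applied to both
inputs; for binary adjacency rows with equal row sums the two metrics
order pairs identically, so the baseline is unaffected by the choice.

All gradients (through the masked softmax, the ELU aggregation, the
classifier head and the decoder) are derived and implemented
explicitly in numpy; a finite-difference check in the test suite
verifies them.  One caveat of exact subgradients: at a pre-activation
of exactly 0, ReLU's derivative is taken as 0, which can differ from a
two-sided finite difference at that single point.

## Synthetic data

The generator emulates the one structural property the method relies
on: latent sample groups whose members share mean shifts on a subset
of informative features, making same-group samples more correlated
than cross-group samples (an assortative correlation graph).  Each
group draws a Rademacher sign pattern over the informative features;
its mean is a log2-scale baseline (default 6.0, a typical
log-expression magnitude) shifted by `separation × noise_sd × sign`.
Samples are Gaussian around their group mean and passed through a
softplus floor so values stay non-negative like log-transformed
expression.  Defaults: 200 samples, 100 features, a quarter of them
informative, 4 groups, separation 5, noise SD 1 — recoverable but not
degenerate.  The binary task variant uses two groups with a 4:1
majority:minority ratio, mimicking receptor-status imbalance.

What the generator does **not** emulate: count noise and dropout of
scRNA-seq, batch effects, heavy-tailed expression, gene–gene
correlation beyond the shared group shifts, and label noise.  Passing
tests on this data therefore demonstrate that the implementation is
correct and that the pipeline recovers planted assortative structure;
they do not certify performance on real cohorts, where the
correlation graph is far noisier.

## Problem sizes and numerical choices

The study conditions exercised by the tests and the acceptance script
are n=300/m=150 (classification, separation 4) and n=250/m=120
(clustering, 5 groups, separation 5), each PCA-reduced to 50
components before entering the network — full-batch dense linear
algebra at these sizes runs in seconds per training run.  PCA always
mean-centers and never variance-scales, and each component's sign is
fixed so its largest-magnitude loading is positive (platform
reproducibility).  The softmax subtracts the per-row maximum before
exponentiation; NLL is computed from log-probabilities (floored at
1e-300).  Divergence (non-finite loss) aborts training with a
diagnostic rather than returning garbage.  One master seed derives
per-stage seeds by hashing `(master, stage)`, all below 2^31.

On synthetic data the log2(x+1) step is skipped by default because the
generator already produces log-scale values; the transform remains a
flag for raw-scale inputs.

## Evaluation

AUROC is computed by the rank (Mann–Whitney) formula with mid-rank tie
handling; NMI from the contingency table with arithmetic-mean
normalization of the marginal entropies (geometric/min/max available);
ARI by pair counting with chance correction.  These are self-contained
implementations cross-checked in the tests against exhaustive pair
enumeration, explicit formula oracles and scikit-learn.

## Known limitations

* Dense `n×n` attention: memory and time scale quadratically in
  samples; the implementation targets cohort sizes up to a few
  thousand, not atlas-scale single-cell data.
* Single attention layer only; no multi-layer stacks.
* The classifier's AUROC reporting assumes binary tasks; multi-class
  runs train and predict but report no AUROC.
* No survival analysis, baseline model zoo, or plotting utilities —
  embeddings and matrices are written as TSV for external tools.
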