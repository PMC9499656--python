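#!/usr/bin/env bash
# Full shell workflow: simulate -> preprocess -> graph -> cluster -> attention.
set -euo pipefail

WORK=$(mktemp -d)
echo "working in $WORK"

# 1. simulate a 3-group cohort
exprgat simulate --n 120 --m 60 --k 3 --separation 5 --seed 0 --out "$WORK/data"

# 2. PCA-reduce the expression matrix
exprgat preprocess "$WORK/data/expression.tsv" "$WORK/features.tsv" --pca 30 --seed 0

# 3. build the correlation-kNN adjacency at 10% density
exprgat build-graph "$WORK/features.tsv" "$WORK/adjacency.tsv" --density 0.1

# 4. train the clustering autoencoder and cluster the embeddings
exprgat embed-cluster -f "$WORK/data/expression.tsv" -l "$WORK/data/labels.tsv" \
    --pca 30 --k 3 --epochs 300 --seed 0 --out "$WORK/run"

# 5. extract the max-over-heads attention matrix from the trained model
exprgat extract-attention --model "$WORK/run/model.npz" -f "$WORK/features.tsv" \
    -g "$WORK/run/adjacency.tsv" --out "$WORK/attention.tsv"

echo "metrics:"
cat "$WORK/run/metrics.json"
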