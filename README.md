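# mdignn

Cancer driver gene prioritization on **directed** gene networks with a
magnetic-Laplacian graph neural network.

Most network-based driver-gene predictors flatten gene regulatory
networks into undirected graphs, discarding who regulates whom. `mdignn`
keeps the orientation: the directed graph is encoded as a complex
Hermitian operator whose magnitude carries undirected connectivity and
whose phase carries edge direction. Multi-omics gene features (mutation
rate, differential methylation, differential expression per cancer type),
system-level gene properties, and random-walk topology embeddings are
propagated through complex spectral convolutions, refined by channel and
spatial attention, and scored with a sigmoid head into one
driver-probability per gene. The package is aimed at computational
biologists who have directed edge lists and per-sample omics matrices and
want ranked driver candidates plus a defensible cross-validated
evaluation.

## The operator at the core

For a directed graph with binary adjacency A and phase parameter q ≥ 0:

    S(u,v)   = ½ (A(u,v) + A(v,u))                 symmetrized adjacency
    Θ(q)(u,v) = 2πq (A(u,v) − A(v,u))              phase matrix
    H(q)      = S ⊙ exp(iΘ(q))                     Hermitian adjacency
    L(q)      = I − D^{−1/2} S D^{−1/2} ⊙ exp(iΘ(q))   magnetic Laplacian

L(q) is Hermitian positive-semidefinite with eigenvalues in [0, 2];
q = 0 recovers the classical normalized Laplacian (undirected GCN), while
q = 0.25 maps one-way edges to purely imaginary entries. Convolution
layers apply Chebyshev filters of L̃ = L − I,

    X(ℓ) = σ( X(ℓ−1) W_self + L̃(q) X(ℓ−1) W_neigh + B ),

with a complex ReLU σ(z) = z·1[Re(z) ≥ 0]. See `docs/methods.md` for the
full model, training protocol, and the synthetic benchmark design.

## Worked example

Simulate a desk-scale benchmark (200 genes, 20 planted drivers, 60
labeled negatives, 4 cancer types × 20 tumor/normal pairs), featurize,
cross-validate, and rank candidates:

```python
from mdignn import (SimSpec, simulate_benchmark, featurize, RunConfig,
                    cross_validate, train_full, rank_candidates)

spec = SimSpec(n_genes=200, n_drivers=20, n_nondrivers=60,
               n_cancer_types=4, samples_per_type=20, seed=42)
graph, cohort, sys_table, labels = simulate_benchmark(spec)

cfg = RunConfig(seed=42)                      # q=0.25, 64 filters, 2 layers
feats = featurize(graph, cohort, sys_table, cfg)
print(graph.n_nodes, graph.n_edges, feats.n_features)
# 200 1614 38      (12 biological + 10 SYS + 16 topological columns)

report = cross_validate(graph, feats, labels, cfg, n_folds=5, n_repeats=1)
print(report.summary().round(3))              # auroc 1.0, aupr 1.0, mcc 1.0

params, hist = train_full(graph, feats, labels, cfg)
table = rank_candidates(params, graph, feats, labels, cfg, threshold=0.9)
print(int(table.candidate.sum()), int(table.novel.sum()))
# 20 0    (all 20 planted drivers recovered above 0.9; no false novels)
print(table.head(3)[["gene", "probability", "label_status", "rank"]])
#   gene  probability label_status  rank
#   G056        1.000     positive     1
#   G190        1.000     positive     2
#   G106        0.999     positive     3
```

With the default strong planted signal (δ = 2, ρ = 2) the 5-fold
cross-validated AUROC is 1.0 and training stops by early stopping around
epoch 450 of the 3000-epoch cap. The interesting behavior is at the
margins: at δ = 0, ρ = 1 the same pipeline scores at chance
(AUROC ≈ 0.5), and on graphs where driver identity lives *only* in edge
orientation the q = 0.25 model clearly beats the q = 0 (undirected)
ablation — both properties are asserted in `tests/test_acceptance.py`.

The same workflow is available from the shell:

```bash
mdignn simulate --seed 42 --out bench/
mdignn featurize --bench bench/ --seed 42 --out features.tsv
mdignn evaluate  --bench bench/ --seed 42 --cv 5x1 --metrics-out metrics.tsv
mdignn rank      --bench bench/ --seed 42 --threshold 0.9 --out candidates.tsv
mdignn build-graph --source name=KEGG,kind=directed,path=kegg.tsv \
                   --source name=STRING,kind=undirected,path=string.tsv,min_score=0.85 \
                   --out merged.tsv
```

Real data enter as TSV edge lists (source, target[, score][, level]),
per-(cancer type, channel) omics matrices, a SYS feature table, and
one-symbol-per-line label files; confidence thresholds are strict
(`score > min_score`), undirected sources expand to reciprocal edge
pairs, and duplicate edges merge with the union of their source tags.

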