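# Methods

## Problem setting

Cancer driver genes are identified here as a semi-supervised node
classification problem on a directed gene network: a minority of genes is
labeled positive (known drivers), a larger set is labeled negative, and
most genes are unlabeled. The method is transductive — one fixed graph
contains labeled and unlabeled genes, and every gene receives a driver
probability.

## The magnetic Laplacian

Gene regulation is directional, and discarding orientation loses exactly
the information that distinguishes a regulator from its targets. Given the
binary asymmetric adjacency A of the directed graph, the package builds

* the symmetrized adjacency `S(u,v) = (A(u,v) + A(v,u)) / 2`, entries in
  {0, ½, 1}, carrying undirected connectivity;
* the phase matrix `Θ(q)(u,v) = 2πq (A(u,v) − A(v,u))`, skew-symmetric,
  carrying orientation;
* the Hermitian adjacency `H(q) = S ⊙ exp(iΘ(q))`;
* the normalized magnetic Laplacian
  `L(q) = I − D^{−1/2} S D^{−1/2} ⊙ exp(iΘ(q))`,
  with D the degree matrix of S.

`L(q)` is Hermitian positive-semidefinite with real eigenvalues in
[0, 2]. A reciprocal edge pair has zero phase; a one-way edge at
q = 0.25 becomes a purely imaginary entry (maximal direction contrast);
q = 0 recovers the classical symmetric normalized Laplacian, i.e. an
ordinary undirected GCN operator.

Spectral filters are Chebyshev polynomials of the shifted operator
`L̃ = L − I`, evaluated with the three-term recurrence
`T₀ = I, T₁ = L̃, T_k = 2 L̃ T_{k−1} − T_{k−2}` — no eigendecomposition.
The shift uses the proven spectral bound λmax = 2 rather than the
graph-specific maximum; this is the standard Chebyshev rescaling, keeps
the shifted spectrum inside [−1, 1] on every graph, and makes the
operator reproducible without an eigensolve.

Numerical choices:

* degree-zero genes get a zero entry in `D^{−1/2}` (their row of L is an
  identity row) rather than invented self-loops;
* components of `H` at machine-epsilon scale relative to the entry's
  magnitude are snapped to exact zero, so q = 0.25 produces exactly
  `±i·S(u,v)` for one-way edges. This matters because the complex ReLU
  keys on the sign of the real part, and `cos(π/2)` is not exactly zero
  in floating point;
* all operators are complex CSR matrices; there is no real/imaginary
  block-matrix expansion at the linear-algebra level.

## Features

Per gene and cancer type, three omics summaries: mean mutation
indicator/frequency across tumor samples; mean tumor−normal methylation
beta difference across matched pairs; mean log2 tumor/normal expression
fold change across matched pairs. With C cancer types this is a 3·C
biological block (48 columns in the 16-type pan-cancer setting). Mutation
input may be binary indicators or per-sample frequencies; both are
averaged uniformly. A 10-column system-level (SYS) block — ohnolog
status, two essentiality measures, tissue expression breadth, four network
topology statistics, complex membership, and miRNA-target count — is
consumed as a precomputed table, since these properties come from external
curation. All feature columns are z-scored over all graph nodes before
training. The standardization is label-free, so computing it on the full
graph leaks nothing across cross-validation folds; it is also required in
practice for stable complex-valued training.

### Topological enhancement

16-dimensional node embeddings from random walks + skip-gram (node2vec
with unbiased walk parameters p = q_walk = 1): 10 walks of length 80 per
node, context window 5. Walks run on the symmetrized graph — directed
regulatory networks contain many sink genes where a directed walk would
stop immediately, leaving them under-sampled. The skip-gram with negative
sampling (5 negatives, unigram^{3/4} noise distribution, 5 epochs, linear
learning-rate decay from 0.025) is a vectorized numpy implementation;
within a mini-batch, updates hitting the same node are averaged rather
than summed, which keeps the batched approximation of sequential SGD
stable on hub-dominated graphs. Embeddings are computed once on the full
graph before cross-validation splitting; they never see labels.
Under a fixed seed the embedding is invariant to the order in which edges
arrive from disk, because node indexing is canonical (lexicographic);
exact invariance to renaming genes is not guaranteed, since skip-gram
updates couple all training pairs through their ordering.

The concatenated matrix is 48 + 10 + 16 = 74 columns in the pan-cancer
configuration; ablation flags drop the SYS block (58 → 48) or the
topological block (74 → 58).

## Model

Two magnetic convolution layers on complex activations,

    X(ℓ) = σ( X(ℓ−1) W_self(ℓ) + L̃(q) X(ℓ−1) W_neigh(ℓ) + B(ℓ) ),

with σ the complex ReLU `z ↦ z·1[Re(z) ≥ 0]` (boundary kept). The
(self, neighbor) pair is the order-1 Chebyshev filter; configuring a
higher order K adds one weight matrix per extra polynomial term. Real
input features enter with zero imaginary part. The final complex N×64
activations are unwound to a real N×128 matrix `[Re | Im]` — pooling,
sigmoids and max operations are real-valued, and the concatenation
preserves all information.

Attention is applied once, after the last convolution: channel attention
(average-pool over genes → two-stage MLP with reduction ratio r = 8,
128 → 16 → 128 → sigmoid → per-channel weights), then spatial attention
(per-gene average- and max-pool across channels → width-7 1-D convolution
along the canonical gene order, padding 3 → sigmoid → per-gene weights).
Channel attention pools by averaging only; spatial attention uses both
average and max pooling. "Spatial" positions are graph nodes in canonical
order; spatial attention is therefore order-dependent by construction,
which the fixed lexicographic node order makes deterministic. A single
linear layer (128 → 1) plus sigmoid produces the driver probability.
Dropout (rate 0.5) is applied once, after attention, training mode only.

Weights are Glorot-uniform, drawn independently for real and imaginary
parts; biases start at zero; everything is seeded. In GCN ablation mode
q is forced to 0 and the imaginary weight parts are fixed at zero, so the
whole pipeline stays real — tests verify it then matches an independent
real-arithmetic implementation to 1e−8.

### Training machinery

The training loop differentiates through the full model with a small
in-repo reverse-mode automatic-differentiation engine over real numpy
arrays; complex activations are carried as explicit (real, imaginary)
tensor pairs, so all gradients are ordinary real calculus. The engine
supports exactly the operations the model needs (broadcast arithmetic,
dense and constant-sparse matmul, sigmoid/ReLU/softplus, axis reductions,
argmax-routed max, concatenation, the width-7 convolution) and an Adam
optimizer with coupled L2 weight decay. An end-to-end finite-difference
gradient check and an exact-equality test against the plain-numpy
inference path guard it.

## Training protocol

Full-batch Adam, learning rate 1e−3, weight decay 5e−3, at most 3000
epochs with early stopping after 100 epochs without validation-loss
improvement; the best-validation parameters are restored. The loss is
class-weighted binary cross-entropy on labeled nodes only, with positive
weight N_neg/N_pos of the training mask (driver labels are heavily
outnumbered). Each epoch independently drops a fraction (default 0.1) of
directed edges and rebuilds L̃ for that epoch — DropEdge-style
regularization; validation and test always use the full operator.

Evaluation is repeated stratified 5-fold cross-validation (fold
assignment seeded per repeat, seeds 0..repeats−1); within each training
portion a stratified 10% split drives early stopping, so test folds never
influence training. Metrics: AUROC (rank statistic), AUPR (step-function
precision-recall integration), and threshold-0.5 confusion-matrix metrics
(accuracy, sensitivity, specificity, precision, MCC; MCC is 0 when a
marginal factor vanishes). For candidate discovery the model is retrained
on all labeled genes and every gene is scored; genes with probability
strictly above 0.9 are candidates, and candidates that are not known
positives are the novel set.

## Synthetic benchmark

The generator emulates the *shape* of a pan-cancer study at desk scale,
not TCGA marginals. Defaults: 400 genes, 40 planted drivers, 120 labeled
negatives, 4 cancer types × 30 tumor/normal pairs, effect size δ = 2
(driver feature shift in noise-sd units), connectivity multiplier ρ = 2.
The graph is a directed preferential-attachment model in which drivers
emit ρ-fold more edges and attach to each other ρ-fold more often; 30% of
edges get a reciprocal partner, emulating the undirected PPI component.
Omics channels use distributions with the correct support — Bernoulli
mutation indicators (base rate 0.05), Beta methylation betas
(concentration 20), log-normal expression — with driver means shifted by
δ-scaled amounts; the SYS table mixes Bernoulli flags and Gaussian
columns with δ-scaled driver shifts. At δ = 0 and ρ = 1 drivers are
exchangeable with all other genes by construction, and the pipeline must
score at chance — this null calibration is asserted in the acceptance
tests.

A second generator plants the signal *only* in edge orientation: an
Erdős–Rényi undirected skeleton is drawn class-blind, then each edge gets
exactly one direction, pointing away from an incident driver with
probability 0.9. Degrees and the symmetrized adjacency carry no class
information, so the q = 0 model is blind while q = 0.25 can read the
out/in phase imbalance — the acceptance test requires the phase model to
strictly beat the undirected one. This comparison uses the biological+SYS
features without the walk embedding: the undirected skeleton is
class-blind by construction, so symmetrized-walk embeddings add only
noise, and dropping them keeps the five-seed comparison quick.

What passing these tests does and does not show: the generator verifies
that the implementation recovers planted signal, is calibrated under the
null, and extracts direction information — it does not demonstrate
biological fidelity to TCGA cohorts, real network noise, or literature
label quality.

## Problem sizes and budgets

All shipped tests and the acceptance checks run on the desk-scale
defaults above (400-gene graphs, ≤ 16 pseudo-cancer types); recovery and
calibration checks use 5-fold cross-validation with 1 repeat per seed,
3–5 seeds per condition. These sizes were chosen so the whole suite
completes in minutes on a single CPU while still exercising every stage
at realistic class imbalance (40:120 labeled, 240 unlabeled).

## Known limitations

* The spatial-attention convolution reads genes in lexicographic order;
  the learned kernel is therefore a generic smoothing over an arbitrary
  but fixed ordering, not a biologically meaningful neighborhood.
* The tilde operator is defined as L − I (spectral bound rescaling); if a
  graph's true λmax is far below 2 the filter sees a compressed spectrum.
* Mutation "rate" accepts binary indicators or frequencies without
  distinguishing them; callers mixing the two conventions across cancer
  types will get blended scales (the z-scoring absorbs most of this).
* Confidence scores act only as ingestion filters; the spectral operator
  is built from the binary adjacency, so a 0.51-confidence edge and a
  0.99-confidence edge are equivalent downstream.
* The skip-gram embedding is asymptotically but not exactly invariant to
  gene renaming (see above).
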