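# Methods

## Model

The method is transductive link prediction on a fixed heterogeneous
graph. Nodes are lncRNAs, diseases and miRNAs in the fixed order
[lncRNA, disease, miRNA]; the adjacency matrix X stacks intraclass
similarity blocks S on the diagonal and binary interclass association
blocks Z off-diagonal, with transposes in the mirrored positions so X
is symmetric.

**Similarity kernels.** Disease similarity is Wang-style semantic
similarity over a disease-ontology DAG: the profile of disease W
assigns 1 to W and to each ancestor d the maximum of Δ times the
profile value of any of d's children inside W's ancestor closure,
computed by dynamic programming in reverse-topological order (multiple
inheritance is handled by the max; ties are order-independent). The
decay Δ defaults to 0.5, the conventional value; it is exposed in the
configuration (`delta`) and must lie in (0,1). Similarity is the
shared-term overlap normalised by the two semantic values, which is
symmetric, 1 on the diagonal and 0 for diseases in disconnected
ontology components (no virtual shared root is inserted). RNA
functional similarity is best-match averaging of disease similarities
over the two RNAs' associated-disease sets; an RNA with no known
disease associations gets similarity 0 to every other entity and 1 to
itself, keeping the S block a valid similarity matrix (the 0/0 case of
the best-match formula is undefined otherwise).

**Graph operators.** The GCN feature matrix is the row-normalised X
*without* self-loops; all-zero rows stay zero so isolated nodes do not
produce NaNs. The propagation operator adds self-loops literally
(X̂ = X + I, so a unit similarity diagonal becomes 2) and applies
symmetric Laplacian normalisation X̃ = E^{−1/2} X̂ E^{−1/2} with
E_ii = Σ_j X̂_ij. For symmetric non-negative input the spectral radius
of X̃ is ≤ 1, which keeps repeated propagation non-expanding. Matrices
are dense; at the intended scale (≈150–1,200 nodes) dense linear
algebra is faster and simpler than sparse.

**Encoder and classifier.** Each GCN layer computes
act(X̃ · H · W) with Glorot-uniform seeded initialisation. Hidden
layers use ReLU. The final layer's activation is configurable
(`relu` default, `softmax`, `identity`): a literal row softmax over
the embedding dimension collapses all node representations toward the
simplex centre, and in our experiments the model then never leaves
chance-level loss (≈0.693), so row softmax is kept only as an optional
reading, not the default.

Each candidate (lncRNA, disease) pair is tokenised as the length-2
sequence [z_lnc, z_dis] of GCN embeddings. An encoder layer applies
multi-head scaled dot-product attention — per head, separate learned
query/key/value projections of dimension d/heads, attention weights
softmax(QKᵀ/√p_k) whose rows sum to 1 by construction, head outputs
concatenated and linearly projected — followed by residual Add and
per-token LayerNorm (ε = 1e−5) with learned gain and bias, then a ReLU
feed-forward block (width multiplier 4) with a second Add & Norm.
Both tokens' outputs are concatenated and a sigmoid-activated linear
head yields the association score. The loss is mean binary
cross-entropy with scores clamped to [1e−7, 1−1e−7] before the
logarithm; the mean (not the bare sum) keeps the learning rate
meaningful across batch sizes.

**Training.** Full-batch Adam (lr 1e−3, 200 epochs, seeded). Three
regularisers matter on small graphs and are on by default:

- *dropout 0.4* on the attention and feed-forward outputs (training
  mode only);
- *decoupled weight decay 0.01* on matrix-shaped weights;
- *edge dropout 0.3*: every epoch a fresh random 30% of the known
  lncRNA–disease edges is removed from the adjacency before
  renormalisation. Without this the classifier learns to read a
  training pair's own edge out of the graph — training loss goes to
  zero while held-out pairs, whose edges are masked, gain nothing.
  Edge dropout forces prediction from indirect paths, the regime every
  evaluated pair is actually in.

All of these were chosen by validation experiments on synthetic
benchmarks; none are claimed from prior literature except the GCN
depth (2) and embedding size (128).

The whole model runs on a small reverse-mode automatic-differentiation
engine over NumPy arrays (`gcnlda.nn`) with exactly the primitives the
architecture needs. Analytic gradients are verified against central
finite differences, per primitive and through the full model, at
relative tolerance 1e−4.

## Evaluation protocol

Negative pairs are sampled uniformly without replacement from unknown
(lncRNA, disease) pairs, 1:1 with the positives by default, once per
repeat so no negative leaks across folds. A stratified 20% of labeled
pairs is held out as the test set; the remaining 80% is split into five
stratified folds (per class, and in total, fold sizes differ by at most
one). For fold k the model trains on the other four folds with fold
k's *and the test set's* positive edges masked out of Z_ld (both
symmetric positions), then scores fold k; the fold mean is the CV
result. The final test evaluation trains once on all five folds with
only test positives masked.

Masking removes direct label leakage through the adjacency. One
indirect channel remains by design: the functional-similarity blocks
are computed once from the full association matrix, following the
stated protocol. A stricter variant (`refit_similarity=True`)
recomputes S_ll from the masked Z_ld per fold; it is off by default to
match the protocol as specified, and the residual channel is weak
because similarities aggregate over whole disease sets.

Metrics: AUC (trapezoidal, equal to the Mann–Whitney pair statistic
with ties at ½), AUPR by descending-score step integration (no
trapezoidal interpolation, which is optimistic for PR curves), and
threshold-0.5 accuracy, F1, precision, recall and Matthews correlation.
Undefined denominators (e.g. MCC with an empty class) return 0 with a
logged warning so sweep tables stay total. Method comparison uses the
two-tailed pooled-variance (equal-variance) Student t-test.

The ablation harness evaluates: interclass-only (S blocks replaced by
identity), intraclass-only (Z blocks zeroed), and the full graph; and
transformer variants with the residual Add, the LayerNorm or the
feed-forward block disabled (disabling Add turns LayerNorm(f(x)+x)
into LayerNorm(f(x))). The sweep harness grids GCN depth against
embedding size and reports CV AUC per cell.

## Synthetic benchmark

The generator emulates a curated LDA corpus at desk scale. A rooted
ontology DAG is grown with one branch per latent group directly under
the root; each further term attaches 1–2 parents within its own
branch, so branches are subtrees and the graph is acyclic by
construction. Diseases are ontology terms; a disease's group is its
branch, so semantic similarity genuinely correlates with group
membership, mirroring the premise that similar diseases share RNAs.
lncRNAs and miRNAs get uniform random groups. Every association matrix
entry is an independent Bernoulli draw: probability `p_in` when the
two entities' groups match, `p_out` otherwise. All randomness flows
from one seed through independent child streams, so each artifact is
reproducible regardless of generation order. The default preset is 60
lncRNAs, 40 diseases, 50 miRNAs, 80 ontology terms, 4 groups,
p_in = 0.3, p_out = 0.02.

**What passing tests do and do not show.** Within a matched group
block the edges are i.i.d., so once a held-out pair's edge is masked,
*no* information in the remaining graph distinguishes it from a
matched non-edge: the best any method can do is recover group
membership. An oracle given the true groups attains mean CV AUC ≈ 0.82
and AUPR ≈ 0.78 in expectation under the default preset (realisations
vary by a few points with the seed). The model's mean CV performance
sits at or near this ceiling, which is the right yardstick for this
generator; numbers far above it on real data would reflect
richer structure (degree heterogeneity, nested subtypes, shared
pathways) that the i.i.d. block model deliberately does not emulate.
The generator also does not mimic real identifier vocabularies or the
long-tailed degree distributions of curated databases.

## Problem sizes and runtime

The test suite and the acceptance script use the default preset
(150-node graph, ≈400 labeled pairs) for end-to-end runs, a reduced
20/15/12 benchmark for mechanics tests, and 2–3-epoch configurations
for shape-only harness checks; these sizes are the package's chosen
desk-scale defaults and complete in a few minutes on one CPU. Kernel
and metric oracle checks run at the sizes stated in their tests
(DAGs ≤ 30 terms, matrices ≤ 200 nodes, 1,000 random score sets,
all confusion grids with ≤ 20 counts).

## Known limitations

- Dense matrices only; graphs beyond a few thousand nodes would need a
  sparse propagation path.
- The transformer sees exactly two tokens per pair. How node
  embeddings feed the classifier is the one genuinely open bridge in
  the architecture; the 2-token design is minimal and symmetric, but
  longer context (e.g. neighbourhood tokens) is unexplored here.
- Training is full-batch; mini-batching would be needed for much
  larger pair sets.
- Diseases absent from the ontology are an error, not silently
  defaulted; callers must supply a complete ontology.
- The equal-variance t-test assumes approximately normal, equal-spread
  fold metrics; with five folds it is indicative, not definitive.
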