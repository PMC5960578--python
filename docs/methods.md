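# Methods

## Model

`lmpairnet` predicts associations between diseases and composite
(lncRNA, miRNA) pairs. The unit of evidence for a *known* association is a
triangle: a disease–lncRNA edge, a disease–miRNA edge and an lncRNA–miRNA
interaction co-occurring. The model assumes that functionally similar pairs
associate with similar diseases, and propagates that assumption with a damped
walk count (KATZ measure) on a heterogeneous block matrix.

### Network construction

Three bipartite layers are built from edge lists: G₁ (lncRNA × disease),
G₂ (miRNA × disease), G₃ (lncRNA × miRNA). The tripartite filter keeps the
entity intersections (shared disease vocabulary of G₁/G₂, shared lncRNAs of
G₁/G₃, shared miRNAs of G₂/G₃) and retains only edges participating in at
least one triangle; lncRNAs/miRNAs with no retained disease edge are pruned.
The disease–pair network enumerates the **full cross product** of retained
lncRNAs × miRNAs in row-major order (pair (lᵢ, mⱼ) has index i·n_m + j), so
the pair similarity inherits a Kronecker structure. `DP[p, d] = 1` iff the
triangle exists. A size guard (2·10⁶ pairs) protects the full mode; a
`pairs="interacting"` option restricts pair vertices to observed lncRNA–miRNA
interactions, at the cost of the structured evaluation (the pair similarity is
then a dense slice of the cross-product matrix).

### Similarity layers

**Disease semantic similarity.** The hierarchy is a child→parent DAG
(multiple parents allowed). For disease D, the contribution of a term t in
T(D) = {D} ∪ ancestors(D) is C_D(D) = 1 and
C_D(t) = max{Δ·C_D(c) : c child of t, c ∈ T(D)} — contributions decay along
the best path back to D. Δ = 0.5 by default (exposed as `delta`; values in
(0, 1)). Similarity is the shared-ancestor mass normalized by the two semantic
values; it is 1 on the diagonal, 0 exactly when the ancestor sets are
disjoint. Diseases absent from the hierarchy are treated as isolated terms
(semantic similarity 0 to everything, with a warning), so the integrated
similarity falls back to the interaction-profile branch.

**GIP kernels.** sim(x, y) = exp(−γ‖IP(x) − IP(y)‖²) on binary association
profiles, γ = 1 / (mean squared profile norm) over the compared entities —
disease profiles are columns of the adjacency, gene profiles are rows, each
normalized over its own entity count. The diagonal is pinned to exactly 1. An
all-zero profile matrix is an error (undefined bandwidth). The disease-side
kernels from G₁ and G₂ are combined as √(GIP₁·GIP₂); by default both kernels
are computed on the triangle-restricted vertex sets (`gip_scope="restricted"`),
matching the prediction universe; `"full"` uses all genes of each layer.

**Functional and integrated gene similarity.** Best-match average of the
*semantic* disease similarity between the two genes' associated disease sets
(a `funsim_base="integrated"` switch uses the integrated disease similarity
instead). A gene whose disease set is empty gets functional similarity 0
against every other gene (self-similarity 1) — the conservative
no-information value, since the defining ratio is otherwise 0/0. Integrated
gene similarity is the unconditional mean of functional and GIP similarity —
unlike the disease integration there is no zero-branch.

**Pair similarity.** For pairs p = (lᵢ, mⱼ), q = (l_a, m_b): `average` is
(lncSim + miRSim)/2 = (lncSim ⊗ J + J ⊗ miRSim)/2; `sqrt` is
√(lncSim·miRSim) = √lncSim ⊗ √miRSim; `centre` is the Euclidean distance of
(lncSim, miRSim) from the grand means of the two gene matrices (diagonals
included in the means). The centre scheme is a distance used verbatim as a
similarity and is deliberately not inverted; it has no Kronecker structure and
is always materialized. Average/sqrt are materialized densely up to 4096 pairs
and evaluated as structured operators (`matmul`) beyond that.

### KATZ scoring

With P = PairSim, B = DP, D = DisSim, the block matrix M = [[P, B], [Bᵀ, D]]
is scored by S = Σ_{l=1..K} γˡ Mˡ and the pairs × diseases block S₁₂ is the
prediction matrix. K ∈ {2, 3, 4} uses explicit closed-form expansions (the
length-l block walks from the pair side to the disease side, e.g.
S₁₂(2) = γB + γ²(PB + BD)); larger K iterates the block recursion
(X₁₂, X₂₂) ← (P X₁₂ + B X₂₂, Bᵀ X₁₂ + D X₂₂), which touches P only through
products with n_p × n_d matrices and therefore works with the structured pair
similarity without materializing Mˡ. Defaults γ = 0.01, K = 2. The
infinite-sum form (I − γM)⁻¹ − I is provided for validation only; it checks
γ·ρ(M) < 1 via a dense eigendecomposition and is intended for modest sizes.

Ties in the final ranking break deterministically by ascending
(disease index, pair index).

### Cross-validation

Positives are the known edges; candidates are all cells with no known
association (globally, or per disease column with `per_disease`). Per fold the
held-out edges are zeroed in `DP`, S₁₂ is recomputed, and each held-out score
is converted to a tie-aware percentile within that fold's candidate score
distribution. A candidate's percentile within its own distribution is uniform,
so the fold-pooled AUC is the mean held-out percentile — exactly the
Mann–Whitney probability that a held-out association outranks a random
candidate — and the pooled percentiles against a uniform midpoint grid give
the ROC. This pooling rule is threshold-consistent across folds of different
candidate distributions. k-fold partitions are drawn per repeat from
`default_rng(SeedSequence([seed, repeat]))`; the same seed reproduces the
per-repeat AUC list exactly. AUCs below 0.5 are reported as-is.

Similarity matrices are **not** recomputed per fold by default — they derive
from the gene-level networks, and only the disease–pair adjacency is masked.
`strict_masking` additionally removes each held-out triangle's disease–lncRNA
and disease–miRNA edges from G₁/G₂ and rebuilds every similarity layer per
fold (markedly slower; available in `cross_validate` and the CLI).

For K = 2, masking a single edge changes S₁₂ by an exact closed-form rank-1
update (−γ on the cell, −γ² on the pair-similarity column into the disease
column and the disease-similarity row into the pair row); LOOCV uses this fast
path, verified in the tests against full recomputation.

## Synthetic data

The generator emulates the *shape* of curated association data, not any real
database's marginals: balanced communities over diseases/lncRNAs/miRNAs;
Bernoulli edges with probability p_within inside the matched community and
p_between across (0.5/0.05 for associations, 0.6/0.05 for interactions);
a rooted disease tree whose subtrees align with communities (branching
factor 3), so semantic similarity carries the same block signal
(`dag_mode="random"` decouples them for ablation). Default sizes 30 diseases /
40 lncRNAs / 35 miRNAs, 3 communities, yield ~770 triangles and end-to-end
runs in well under a minute; these sizes were chosen as the desk-scale
benchmark and are used by the acceptance script. Generation is fully
deterministic given the seed; a bounded retry loop guarantees at least one
triangle. What passing tests on this generator show is that the pipeline
recovers planted block structure through all of its layers — not that it
matches the performance numbers attainable on curated human data, whose degree
distributions are far more skewed.

`null_config` produces the density-matched no-structure control: one
community, with both probabilities of each layer set to the expected mixed
density of the structured configuration, so signal and null runs differ only
in community structure.

## Known limitations

- **The cross-validation null is not at chance.** On no-structure data the
  5-fold AUC sits near 0.70–0.73, not 0.5: a held-out cell's triangle
  guarantees its lncRNA and miRNA each carry a disease edge, so other retained
  known edges sharing a gene contribute γ² walk mass that random candidate
  cells lack, and the similarity layers are computed from the unmasked
  gene-level networks. Strict masking removes the similarity channel but not
  the shared-gene topology (null ≈ 0.70). Absolute cross-validated AUCs from
  this protocol therefore overstate performance relative to a random-graph
  baseline; comparisons *between* settings (e.g. truncation depths, pair
  schemes) remain meaningful. The evaluation machinery itself is unbiased: an
  independent random score field yields AUC ≈ 0.5.
- Identifier harmonization across sources (naming conventions, ontology
  mappings) is left to the caller; ids are matched verbatim after whitespace
  trimming.
- The centre-distance pair scheme requires the dense pair matrix; it is not
  usable at very large pair counts.
- The closed-form inverse validator materializes the full block matrix and is
  quadratic in memory; it is a checking tool, not a production path.
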