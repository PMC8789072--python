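# Methods

## The annotation model

`hieranno` annotates cell clusters, not single cells, against a
hierarchical marker reference — a rooted tree whose nodes are cell types
and whose leaves are the most specific types the reference can resolve.
Every node carries a set of marker-gene symbols; after propagation an
internal node's effective marker set is its own markers united with every
descendant's, so broad types aggregate all the evidence of their subtrees.
Marker symbols are matched case-insensitively (human `SYMBOL` vs mouse
`Symbol` conventions); the expression matrix's original symbols are
preserved in all outputs.

The method is bidirectional: clusters are queried against the reference,
and the reference in turn decides where clustering must be refined. One
round consists of (i) embedding a set of cells, (ii) partitioning it into
communities, (iii) scoring each community against the candidate types of
the current tree position, and (iv) descending. Only the cells assigned to
a type with more than one child are re-embedded and re-partitioned, so the
effective resolution increases exactly along the branches the reference
says are refinable. A branch terminates at a leaf ("leaf-resolved") or at
the first level whose winning candidate fails the evidence gate
("unassigned-at-level-L" — the cell keeps the deepest label it earned).

### Activity score

A cluster *c* is scored against candidate *t* with markers *t₁…t_N* by

    AS(c,t) = Σᵢ Exp(tᵢ,c) · w(tᵢ) / N^r,
    w(g)    = 1 + sqrt((max f − f(g)) / (max f − min f)),

with the following conventions:

- `Exp` is the cluster mean of normalized log expression at the first
  level (`r = 0.6`), and the per-gene z-transform of those means across
  the current round's clusters at deeper levels (`r = 0.3`). At the first
  level the candidate marker sets are large and mostly unexpressed, and a
  z-transform would drag scores down (even negative); deeper candidate
  sets are small and sibling discrimination needs relative, not absolute,
  expression. The z-transform is across clusters (clusters weighted
  equally, population standard deviation); genes constant across clusters
  map to 0; negative z values are kept in the sum. With a single cluster
  the z-transform is undefined and the profile falls back to the mean.
- `f(g)` counts the **leaf** types listing gene *g*, computed once at load
  time. Counting leaves avoids the double counting that propagated
  internal sets would introduce; counting over all nodes is available as a
  configuration switch (`weight_scope="nodes"`). Genes carried only by an
  internal node's own set have f = 0 and are treated as maximally
  specific. When max f = min f the formula is 0/0 and all weights are set
  to 1 (uniform frequency carries no ranking information).
- Markers absent from the expression matrix contribute 0 to the numerator
  but still count in N: a candidate whose evidence is unmeasurable is
  penalized, and N stays a reference-side constant.

### Evidence gate

Beside the score, every candidate receives a one-sided Fisher's exact
p-value for the over-representation of its markers among the genes the
cluster "expresses": the 2×2 table crosses marker membership with
expressed-set membership over the measured gene universe, and the p-value
is the upper hypergeometric tail at the observed overlap. The winner (by
score; ties break to the smaller p, then the lexicographically smaller
name) is accepted only if its own p < 0.05.

"Expressed" is defined as cluster mean expression strictly above its
upper quartile over the gene universe (the cut quantile is configurable).
Three designs were rejected. A `mean > 0` cut is degenerate: over a couple
of hundred cells virtually every gene has a nonzero cluster mean, the
table collapses (zero in both right-hand cells) and every p-value is 1. A
cut on the z profile mis-gates genuine subtypes against intermediate
candidates: an intermediate's propagated set contains its *other*
children's markers, which are below the z median in a single-subtype
cluster by construction, so exactly the clusters that should descend were
being stopped. A median cut on mean expression leaves too little margin
for the same case — roughly half of an intermediate's propagated markers
sit at baseline in a single-subtype cluster and clear a median cut by
chance, leaving the enrichment barely past the sampling noise. The
quartile cut on mean expression is scale-free, works for a single
cluster, concentrates the expressed set on genes distinctly
characteristic of the cluster, and asks the right question — are this
type's markers over-represented among what this cluster expresses
highly.

### Descent rules

- Level 1 scores the global clustering against the root's children.
- Clusters mapped to the same child are merged before that child's round,
  and the merged subset is re-preprocessed jointly.
- A parent with a single child does not re-cluster; the child is scored
  against the whole subset as one cluster and still gated (a single-child
  chain can therefore end "unassigned", preserving the halt semantics).
- Subsets smaller than `min_recluster_cells` (default 10) are scored as
  one cluster.
- The `Uniform` baseline clusters once at a fixed resolution and scores
  every cluster against all leaves in average mode with r = 0.3 — the
  conventional one-shot design the iterative procedure is measured
  against.

## Preprocessing

Input is a raw gene-by-cell count matrix (10x-style MTX triplet or dense
TSV/CSV). Steps, each re-run per subset during descent:

- **QC** (strict inequalities, applied once, before normalization): drop
  cells with mitochondrial fraction > 20 % (symbol prefix `MT-`,
  case-insensitive), total UMI < 500, or detected genes < 200 or > 6000.
  Removal counts are reported per criterion; a cell with exactly 500 UMI
  survives.
- **Normalization**: x = ln(1 + 10 000 · count / cell total). Natural log
  is used (the dominant convention of this software ecosystem); the
  per-cell identity Σ(eˣ − 1) = 10 000 is a tested invariant.
- **Variable genes**: a loess curve (span 0.3, via `statsmodels` lowess)
  of log₁₀ variance on log₁₀ mean over nonzero-variance genes; each
  gene's values are standardized by the trend-predicted sd, clipped at
  √n_cells, and ranked by the variance of the clipped values (descending,
  row order breaks ties); top 2000 kept. The loess fit can interpolate a
  variance outlier that sits alone at a boundary mean — with realistically
  populated mean bins the trend is set by each gene's peers.
- **Scaling**: per-gene z-score across cells (population sd), clipped at
  ±10; constant genes scale to zero.
- **PCA**: top 50 components (capped at min(n_cells − 1, n_genes)),
  centering but not re-scaling the already-scaled matrix; full SVD for
  small problems, seeded randomized SVD otherwise; each component's sign
  is fixed so its largest-magnitude loading is positive, making the
  embedding backend-independent.

## Graph clustering

Exact k-nearest neighbors (k = 20, capped at subset − 1, Euclidean on the
embedding, distance ties to the lower cell index), shared-nearest-neighbor
re-weighting by the Jaccard overlap of neighbor sets (each set includes
the cell itself), edges below 1/15 pruned. Neither the SNN weight formula
nor the prune threshold is canonical; both are configurable.

Louvain is a greedy heuristic, so the partition is the best of several
seeded restarts (5 by default), which makes the result deterministic for a
given (graph, resolution, seed). Graphs of ≤ 12 nodes additionally get 40
hill-climbs from seeded random partitions, each refined to local
optimality under single-node moves and pairwise community merges: tiny
graphs have deep greedy basins that a multi-level sweep cannot escape, and
polishing them costs nothing (at larger sizes the refinement is
quadratically expensive and the sweep is already stable, so it is
skipped). Resolution stays at 1.0 at every round: refinement comes from
re-clustering subsets, not from resolution tuning.

## The synthetic generator

The simulator exists because the reference datasets this class of method
is benchmarked on require external downloads; it emulates the regime the
method targets, with known ground truth. Genes are the tree's markers plus
1000 background genes. Per-gene baseline means are drawn once from a
log-normal (mean 0.5 counts, σ = 0.5); for a cell of leaf L, every marker
owned by a node on L's root-to-leaf path is elevated by that level's
fold-change (default 8), means are rescaled to a per-cell library size
drawn uniformly from 2000–5000, and counts are negative-binomial with
dispersion 2. Because ancestor markers are elevated in all descendant
leaves, broad levels are easier than deep ones — the structure the
broad-to-specific strategy exploits.

What it does **not** emulate: ambient-RNA contamination, doublets, batch
effects, dropout beyond NB sampling, or realistic gene-gene correlation.
Passing tests on this generator demonstrate the machinery is correct and
the multiresolution logic helps in the regime it was designed for; they do
not certify accuracy on real tissues.

Two packaged scenarios:

- `toy_hematopoietic_tree()` — a four-level immune tree (five leaves, ten
  markers per node) for end-to-end recovery tests; with 200 cells per
  leaf and 8-fold markers the iterative run recovers ≥ 95 % of leaf
  labels, and recovery decays as the fold-change approaches 1.
- `sibling_challenge_spec()` — two alveolar sibling leaves elevated only
  3-fold under an 8-fold epithelial parent, beside a strong hematopoietic
  branch. At the global resolution 1.0 the two siblings merge into one
  community, so the one-shot baseline can label at most one of them;
  re-clustering the epithelial cells alone separates them. The sibling
  fold was chosen as the strongest signal that still co-clusters globally.

## Problem sizes and numerical choices

Tests and the acceptance script use 100–200 cells per leaf and ~1000
background genes, the smallest sizes at which the signal eigenvalues of
the marker structure clear the Marchenko–Pastur noise edge of the PCA at
these cell counts; much smaller cell counts with the full gene space put
the method outside its operating regime (mirrored in practice by its
documented sensitivity to k for rare populations — k is configurable and
auto-capped). All randomness is seeded: the simulator from its spec, PCA
and Louvain from the run configuration. Identical (input, configuration,
seed) reproduce byte-identical annotation files; the configuration is
echoed as a `#`-prefixed header in every output TSV.

## Known limitations

- The Fisher-gate construction ("expressed" cut, universe choice) is a
  design decision, not part of the published score; it is config-exposed.
- f-frequency scope, z-transform orientation, SNN weighting and pruning
  are likewise reasoned defaults where the method family leaves details
  unstated.
- No multiple-testing correction across candidates (a raw 0.05 gate, by
  design); no soft/probabilistic assignment; no doublet or ambient-RNA
  handling; exact KNN only (desk-scale datasets).
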