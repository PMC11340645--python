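# Methods

## Model and procedure

celltree grows a binary tree over cells by recursive bipartition.
Preprocessing follows the standard defaults for this family of tools:
cells with fewer than 250 total transcripts are removed (threshold
inclusive), then features detected in fewer than 1 surviving cell, in
that order and in a single pass (no iteration to a fixpoint; a cell is
not re-examined after feature removal). TF-IDF weighting is

    x̃(c,g) = (x(c,g) / Σ_g x(c,g)) · ln(N / df_g)

with natural log and no smoothing offset. A consequence we accept is
that a feature detected in *every* cell has idf = ln 1 = 0 and is zeroed
out; this is the simplest information-retrieval reading of TF-IDF, and
ubiquitous features carry no contrast for partitioning anyway.

At each node the candidate split is the sign pattern of the second left
singular vector of the row-ℓ2-normalized TF-IDF submatrix over the
node's cells. The first singular vector of a non-negative matrix is
non-negative and captures overall intensity; the second is the leading
contrast direction, so its sign bisects the cells along the dominant
axis of transcriptional variation. Components ≥ 0 go to side A
(deterministic tie-break). When LAPACK returns a one-signed basis vector
from a tied singular subspace (it can, e.g. for mutually orthogonal
cells), the vector is split at its mean instead, which reduces to the
sign rule for a centred vector; a vector with relative spread below
1e-8, or a second singular value below 1e-8 of the first, signals a
rank-1 submatrix and the node is kept as a leaf.

The split is accepted iff its Newman–Girvan modularity Q on a similarity
graph over the node's cells strictly exceeds `min_modularity`
(default 0). Q = Σ_i (e_ii − a_i²) is computed from the community
weight fractions; an equivalent form is the double sum
(1/2m) Σ_ij (w_ij − k_i k_j / 2m) δ(c_i, c_j), which the test suite uses
as an independent oracle. Q ≤ 0 means the cut captures no more weight
than a degree-preserving random rewiring — the "any further split is
random" stopping rule. The accepted Q is stored as the node's split
distance (leaves carry 0), and node ids are assigned breadth-first from
root = 0.

### The similarity graph

The graph on which Q is evaluated is dense truncated cosine:
w(i,j) = max(0, cos(x̃_i, x̃_j)) for i ≠ j, zero diagonal. TF-IDF
matrices are non-negative so the clipping is inert there, but it keeps
the graph valid for any transformed input. This is a deliberate
desk-scale choice: a dense n² graph per node is exactly checkable
against the brute-force modularity definition and deterministic, at the
cost of scaling; this package targets matrices of order 10⁴ cells, not
atlas scale, and makes no attempt at the matrix-free streamed
formulation used by production implementations of this algorithm.

### Determinism

Below 512 cells per node the split vector comes from dense LAPACK SVD
(bit-reproducible); above, from Lanczos (`svds`) with a fixed constant
start vector. The sign convention (largest-magnitude component positive)
plus the side-A tie-break make `build_tree` deterministic for a given
matrix, and invariant to cell input order up to node renumbering (tested
on planted data).

## Pruning dialects

- `prune_min_cells(n)`: bottom-up; whenever *either* child of a node
  holds fewer than n cells, both children merge into the parent. A
  binary tree cannot drop a single child, so the whole split is undone;
  one postorder pass reaches the fixpoint because merging never changes
  any node's cell count. Guarantee: every non-root node ends with ≥ n
  cells.
- `prune_min_distance(cutoff)`: top-down from the root, strict `<`, and
  short-circuiting — descendants of a collapsed node are not visited, so
  a deep high-distance node under a low-distance ancestor still
  collapses. This is one defensible reading of a distance-search prune;
  cutoff 0 is the identity.
- `prune_depth(d)` truncates at depth d; `set_root(id)` extracts a
  subtree, preserving original node ids so previously computed overlays
  still cross-reference, and without recomputing distances.
- A collapsed node becomes a leaf with distance 0, keeping the leaf
  invariant; all ops are pure and idempotent, and histories replay
  deterministically (a prefix replay implements undo).

## Overlays and differential expression

Node means are computed over *all* cells in a node including zeros; the
internal consistency check is the weighted-mean recursion
mean(parent) = Σ_child n_child·mean(child) / n_parent (machine
precision). Differential expression between two disjoint cell sets uses
upper-quartile normalization — each cell divided by the 75th percentile
(linear interpolation) of its nonzero counts, rescaled by the median of
those per-cell quartiles so magnitudes stay comparable — then

    log2FC = log2((mean_A + ε) / (mean_B + ε)),  ε = 1 by default

(ε exposed as `pseudocount`; 1 is the conventional choice for count
data). p-values come from the Mann–Whitney U test with tie correction
(scipy's exact method for small tie-free samples, normal approximation
otherwise; two-sided by default with a one-sided flag), q-values from
Benjamini–Hochberg step-up over all features. Features constant across
both groups get p = 1. No pre-test feature filtering is applied.

## Feature store

One little-endian float64 binary column per feature plus a text index
and barcode list. This honors the single-import contract — after
`build_feature_store`, overlays and batch rendering never touch the
source matrix — without requiring a database server. The contract is
enforced by instrumentation counters in the test suite: a batch run
performs exactly one tree parse, one store open and zero matrix reads.

## Rendering

Radial layout: the root owns [0, 2π); children split the parent's span
in proportion to leaf counts (cells-weighted optional — leaf-count
allocation keeps deep small clades readable). Node angle is the span
midpoint. Radii grow in unit steps, or, with branch scaling enabled, by
the parent's split distance floored at 1% of the deepest cumulative
distance so zero-distance edges stay visible. Branch width is
min + (max−min)·log1p(n)/log1p(n_root). Glyphs are label-composition
pies (majority-color optional) or overlay-colored circles on a monotone
two-color linear scale over [min, max] of the node means. SVG is
generated element-by-element (fixed 3-decimal coordinate formatting, so
identical inputs give byte-identical files); PNG export rasterizes this
dialect with Pillow at 2× supersampling. Batch rendering is sequential
by design: determinism over speed.

The `RenderConfig` JSON (schema tag `celltree-config/1`) rejects unknown
keys and round-trips losslessly, and embeds the prune history, so one
config fully reproduces a figure from the unpruned tree.

## Synthetic data

`simulate_block_counts` draws negative-binomial counts with
var = μ + μ²/θ, θ (`dispersion`) shared across features. Each block
gets a disjoint set of marker features whose mean is `marker_fold` × the
baseline inside the block. Defaults — 3 blocks × 50 cells, 500
features, 25 markers/block, baseline mean 2, θ = 5, fold 8 — describe a
small, clearly separated experiment: fold-8 markers are strong (cell
identity genes), θ = 5 is moderate overdispersion, and 500 features keep
the cosine graph well concentrated. What the generator does *not*
emulate: library-size gradients, doublets, ambient RNA, batch effects,
dropout beyond what the NB gives. Passing recovery tests therefore shows
the pipeline is correct and sensitive under clean planted structure, not
that it resolves subtle states in real tissue.

`simulate_random_tree` fabricates valid trees directly (uniform split
distances in (0,1), full binary shape) for exercising pruning, overlays
and rendering independently of clustering.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: 150-cell
matrices for recovery (20 seeds signal + 20 null), ≤ 12-vertex graphs
for the modularity oracle (100 draws), 200 random trees for pruning
guarantees, 100 tree/vector pairs for aggregation conservation, and
5-feature batches. These sizes make every check exhaustive or
near-exhaustive while keeping the full suite in seconds.

## Known limitations

- Dense similarity graphs and dense SVD bound practical input to the
  low tens of thousands of cells.
- The `cluster_tree.json` schema is this package's documented dialect of
  the format family, not a byte-compatible reader for any other tool's
  output.
- Upper-quartile normalization assumes every cell has nonzero counts
  (guaranteed post-filter) and ≥ some spread; cells whose nonzero counts
  are all equal get that value as divisor.
- PNG output is a faithful rasterization of the package's own SVG
  dialect only; arbitrary SVG is out of scope.
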