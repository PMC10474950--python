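# Methods

## Model

`treetop` models a differentiation process as a tree over milestones
(discrete cell states) embedded in a low-dimensional space, with cells
placed continuously along the tree's edges.  Inference proceeds in five
stages, each exposed as a library function and a CLI subcommand.

**1. Embedding.**  All downstream stages operate on an N × d cell
embedding with 2 ≤ d ≤ 50.  Starting from an expression matrix, the
default reduction is 5-dimensional landmark MDS on Euclidean distances
between the (already normalized) expression rows; classical MDS and PCA
are alternatives.  Normalization, QC, highly-variable-gene selection and
batch integration are assumed done upstream — the method inherits
whatever geometry the embedding encodes, and no attempt is made to fix a
topology the embedding does not support.  t-SNE/UMAP coordinates are
deliberately not offered as inference inputs; they distort global
distances.

**2. Clustering ensemble.**  CLARA k-medoids is run L times (default
10 000).  Each run draws k uniformly with replacement from a k-range
(default 3–20), then clusters: PAM (BUILD + SWAP) on each of 5 random
subsamples of size 40 + 2k, assignment of all N cells to the nearest
medoid, keeping the best-scoring subsample solution.  Runs whose
clustering contains a cluster with fewer than `min_cluster_size = 5`
cells are discarded, leaving L′ members.  Child seeds are split from the
master seed with `SeedSequence.spawn`, so member j is reproducible
independently of the other runs.

**3. Connectivity.**  For each member, cluster-to-cluster distances are
the Mahalanobis-like quadratic form
d²(i,j) = (μᵢ−μⱼ)ᵀ(Sᵢ+Sⱼ)⁻¹(μᵢ−μⱼ) on cluster centroids μ and ML
covariances S, so distances respect the shape and spread of the
clusters; a minimum spanning tree over this matrix is the member's
milestone network.  Every cell inherits its cluster's MST degree divided
by the member's cluster count, each per-member vector is scaled so its
maximum is exactly 1, and the L′ vectors are averaged with the
arithmetic mean into the per-cell connectivity c̄ ∈ (0, 1].  The
arithmetic mean (rather than a median) keeps the connectivity gradient
continuous.  High c̄ marks cells far from leaves — branching regions.

**4. Selection.**  Members are ranked by the variance ratio criterion
(Calinski–Harabasz), VRC = [B/(k−1)]/[W/(N−k)], computed on the
one-dimensional c̄ vector under the member's labels.  A member scores
high when its clusters are internally coherent but mutually distinct in
connectivity, which is what a clustering that carves the tree at its
joints looks like.  Comparators used in the selection experiment:
average silhouette width on embedding distances, plain VRC on the
embedding, and a seeded random ranking.  W = 0 yields a +infinity
sentinel; ties among infinities prefer larger k (finer milestones),
then the member index.

**5. Smoothing.**  The chosen member's MST is rooted (see below) and
each root-to-leaf path becomes a lineage.  Principal curves are fitted
by the classic alternation — project cells onto the current curve for an
arc-length parameter, smooth each coordinate against the parameter,
rebuild the curve — initialized with the piecewise-linear curve through
the lineage's cluster centroids.  Cells whose cluster lies on several
lineages (the shared stem before a branching point) have their smoothed
positions and their pseudotimes averaged across those lineages each
iteration, so shared segments coincide and stem pseudotime agrees
between lineages exactly.  Pseudotime is raw arc length in embedding
units from the root end; the milestone network is re-exported with edge
lengths equal to differences of mean milestone pseudotimes, directed
away from the root.  With k = 2 the fit reduces to the straight centroid
segment with pseudotime the projection coordinate.

**Root selection.**  Three modes: a user-supplied start cell (its
cluster becomes the root — the mode used in all experiments, mirroring
benchmarks that hand every method the true start); `max_shared`, the
vertex maximizing the length of the lineage prefix shared before the
first branching point (ties to the lowest vertex id); or seeded random.

## Evaluation metrics

* **cor_dist** — Spearman correlation (clipped below at 0) of all
  pairwise cell geodesic distances along the two milestone networks,
  with each cell placed on its assigned edge at the fractional position
  implied by its pseudotime.
* **him** — 1 − HIM distance, HIM = sqrt((H² + IM²)/2), H the
  normalized Hamming distance between binary adjacency matrices (the
  smaller network padded with isolated vertices) and IM the
  Ipsen–Mikhailov spectral distance with the Lorentzian width γ
  calibrated per size so the empty-vs-complete distance is 1.  Tree
  networks are first simplified by collapsing degree-2 milestones and
  canonically relabelled (AHU encoding rooted at the tree center), so
  the score compares branching topologies and is label-invariant: any
  two linear trajectories score exactly 1.  Both steps can be disabled
  (`simplify=False`, `canonicalize=False`) for a raw adjacency
  comparison.
* **f1_branches** — cells grouped by network edge in each trajectory;
  per-branch-pair Jaccard; recovery = mean over truth branches of the
  best Jaccard, relevance = the same over predicted branches; F1 is
  their harmonic mean.
* **overall3** — geometric mean of the three.  The label is deliberate:
  the four-metric benchmark score also includes a feature-importance
  correlation that requires a trained regression model and is out of
  scope here, so our overall score is not numerically comparable to
  published four-metric scores.

## Synthetic data

The simulator emulates the standard topology taxonomy — linear path,
bifurcation (one degree-3 vertex), multifurcation (one vertex with ≥ 3
downstream leaves), and random trees from seeded Prüfer sequences.
Milestones are placed by rejection sampling so adjacent milestones are
exactly `edge_length` apart and non-adjacent ones at least that far.
Cells are sampled on edges (probability proportional to edge length,
uniform progression) with isotropic Gaussian noise of `noise_sd`, so
ground-truth branch assignment and pseudotime are unambiguous; the root
is milestone M1 by convention.  Expression matrices are produced by an
orthonormal-row linear map of the coordinates plus Gaussian noise, which
preserves pairwise distances exactly before noise.

What this does **not** emulate: count noise (negative-binomial
sampling, dropout), uneven cell-type abundances, batch effects, or
cells concentrated at milestones.  Passing tests on these data show the
machinery is correct and self-consistent — recovery of clean tree
geometry, correct statistic arithmetic, stable behavior across seeds —
not that performance on real scRNA-seq data matches any published
benchmark.

Defaults (`SimulationSpec`): 5 milestones, 300 cells, d = 5,
edge_length = 1, noise_sd = 0.1 (≈ 10% of an edge, enough to blur
cluster boundaries without changing the topology), seed 0.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_runs` (L) | 10 000 | clustering runs; c̄ stabilizes as L grows |
| `k_range` | (3, 20) | cluster counts sampled per run; raise the upper limit for trajectories with many milestones |
| `min_cluster_size` | 5 | filter threshold for retaining a clustering |
| `n_samples`, `sample_size` | 5, 40 + 2k | CLARA subsampling; the standard formulation |
| `selection` | connectivity | ranking criterion; asw/vrc/random for comparison |
| `max_iter`, `tol` | 15, 1e-3 | principal-curve iterations and relative tolerance on total squared orthogonal distance |
| `random_state` | 0 | master seed; all stages are deterministic given it |

## Numerical choices

* **Covariance regularization** (cluster distances): clusters with fewer
  than d + 2 cells, or a pair sum Sᵢ+Sⱼ with condition number above
  1e12, fall back to the diagonal of the covariances; a ridge of
  1e-6·trace/d is added if the diagonal is itself near-singular, and a
  still-singular pair raises an error naming the pair.  Single-cell
  clusters use the global per-dimension variance.  ML (divide-by-n)
  covariances keep degenerate inputs deterministic.
* **MST ties**: Kruskal with edges pre-inserted in (u, v) order, so
  equal-weight edges resolve reproducibly.
* **Smoother**: weighted natural cubic smoothing spline with the penalty
  chosen per coordinate by generalized cross-validation, implemented on
  the Demmler–Reinsch eigenbasis (one eigendecomposition per
  lineage-iteration, shared across coordinates; GCV evaluated on a
  90-point log-spaced λ grid).  The parameter axis is first aggregated
  to at most 100 weighted sites.  Lineages with fewer than 10 distinct
  parameter values use a least-squares line; identical points collapse
  to a zero-length curve.
* **Monotone descent**: a principal-curve iteration that would increase
  the total squared orthogonal distance is rejected and the fit stops,
  so the objective is non-increasing by construction.
* **Assignment ties**: nearest-medoid and branch-assignment ties resolve
  to the lowest index / earliest edge.
* **HIM γ calibration**: solved numerically (Brent) per graph size and
  cached; the spectral density integral uses adaptive quadrature on
  [0, ∞).

## Experiment design

The two scripted studies (`treetop.experiments`) are desk-scale
stand-ins for the full-size protocols, with sizes chosen as the
package's own defaults: the selection comparison uses 10 mixed-topology
datasets (300 cells, noise 0.1), ensembles of L = 300 with k ∈ [3, 8],
and the top 10 members per criterion; the robustness study uses 3
datasets, L ∈ {100, 500, 2500}, 10 master seeds each, at the default
k-range (3, 20).  Both hand every run the true start cell as root hint.
The zero-noise recovery check uses the worked example's simulation
settings with noise 0: 5-milestone bifurcations, 300 cells, L = 500,
k ∈ [3, 8], 20 seeds.

## Known limitations

* Only connected tree topologies: no cycles, no disconnected parts.
* Connectivity is a cluster-level quantity broadcast to member cells;
  cell-level refinement (e.g. by distance to the cluster center) is not
  implemented.
* Cell-to-lineage weights are binary cluster-membership indicators, not
  soft shrinkage weights, so curves near branch points can be less
  smooth than Slingshot's.
* The selection criterion can prefer finer partitions than the
  generating truth on perfectly smooth connectivity gradients; the
  topology metric is robust to this (extra pass-through milestones
  collapse), but milestone counts are not guaranteed to match.
* ASW ranking materializes the N × N distance matrix; fine at desk
  scale, quadratic in memory.
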