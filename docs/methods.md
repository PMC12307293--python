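# Methods

`tmenet` re-implements, as a tested library, an analysis chain used to
characterize immune-cell crosstalk in tumor microenvironments (TME):
ligand–receptor communication strengths aggregated into a weighted
directed cell-type network, hierarchical root/layer analysis of that
network, a 2–4-node motif census scored against a degree-preserving
rewiring null, gene-signature scoring of single-cell and bulk
expression, and unsupervised "barrier-associated" subtyping of bulk
cohorts. Every stage can be exercised on synthetic data in which the
effect to be recovered is planted explicitly, so the pipeline's
statistical behavior is testable without any external download.

## Communication strengths and the cell-type network

For a ligand–receptor pair and an ordered cell-type pair (sender s,
receiver r) the score is a saturating mass-action (Hill) form

    strength(s→r) = L·R / (k_h + L·R),   k_h = 0.5 by default,

where L is the 10%-trimmed mean of log-normalized (counts-per-10k,
log1p) ligand expression in s — geometric mean across subunits for
multi-subunit ligands — and R the analogous receptor level in r.
Strengths lie in [0, 1) and are monotone in both L and R. Cell types
with fewer than 5 cells (`min_cells`) contribute no interactions. This
is a deliberate, documented simplification of full communication-
probability machinery: it preserves the properties the downstream
network analysis needs (nonnegativity, saturation, monotonicity,
per-pair additivity) without carrying an external interaction database.
The edge weight s→r of the cell-type network is the sum of pair
strengths; pathway-level breakdowns are kept per edge. Autocrine
(self-loop) edges are allowed in the network but excluded from the
motif census and reported separately.

Group comparisons (e.g. therapy responders vs non-responders) treat
patients as replicates: strengths are computed per sample, the statistic
is the difference of group means, and the p-value comes from label
permutation with add-one smoothing, p = (1 + #{|d*| ≥ |d|})/(1 + n_perm).
Pooling cells across patients instead would treat cells as exchangeable
replicates and overstate certainty; the per-patient route is the
conservative choice.

## Hierarchy

Edges with weight strictly below 1e-4 are pruned (the at-threshold edge
survives; nodes are never dropped). The root is the node with the
highest weighted outdegree, ties broken lexicographically so the choice
is deterministic. Layers are breadth-first distances from the root
following edge direction; nodes unreachable from the root are reported
separately rather than being forced into a layer. BFS distance is the
simplest rule consistent with hierarchy plots built from a root node; a
longest-path layering (which pushes nodes as deep as their longest
upstream chain allows) is available for acyclic networks via
`layer_nodes(..., method="longest_path")`. Pruning happens before root
selection by default; both orders are trivially composable from the
public functions.

## Motif census

All connected induced subgraphs on k ∈ {2, 3, 4} nodes are enumerated —
each node set counted exactly once, the induced subgraph (every arc
among the chosen nodes) deciding the class. Classes are directed
isomorphism classes, canonicalized as the lexicographic minimum of the
adjacency bit-string over all k! relabelings; at k ≤ 4 this exhaustive
canonicalization is exact and cheap (≤ 24 permutations). There are 2
connected 2-node classes, 13 weakly-connected 3-node classes (labeled
with standard triad-census codes: the feed-forward loop is 030T, the
cycle 030C), and 199 weakly-connected 4-node classes. Each instance is
scored by the sum of its induced edge weights; a class's "sum strength"
is the total over its instances. Induced matching was chosen over
partial (subgraph-monomorphism) matching because motif significance is
conventionally defined on induced counts; counting node sets once (not
automorphism-weighted embeddings) keeps counts interpretable as "how
many cell-type combinations realize this pattern".

The enumeration is vectorized over node subsets (a bit-mask per subset,
classified through a precomputed canonical lookup table), so a full
census on a 15–20-node cell-type network costs milliseconds and the
null ensemble below stays cheap.

## Rewiring null and significance

The null randomizes wiring while holding every node's in- and
out-degree fixed: repeated directed double-edge swaps
(u1→v1, u2→v2) ⇒ (u1→v2, u2→v1), rejecting swaps that would create a
self-loop or duplicate arc, with ⌈10 × |E|⌉ attempted swaps per draw.
Each null network is rewired independently from the observed graph, so
draws are independent rather than successive states of one Markov
chain. Weights ride with their arcs (each arc keeps its tail and
weight, only heads are exchanged), so every draw preserves the degree
sequences *and* the edge-weight multiset exactly — the null for the
sum-strength statistic then asks "is this much weight concentrated in
this pattern, given the weights and degrees we observed?". An
alternative mode shuffles weights over arcs independently.

Per class, both the instance count and the sum strength are compared
with the ensemble: z = (obs − mean)/sd (sample sd; NaN when the null is
degenerate) and an upper-tail empirical p with add-one smoothing,
p = (1 + #{null ≥ obs})/(1 + n_random), so p ≥ 1/(n_random + 1) always.
Count statistics are heavily tied under rewiring (small integer
support), which makes their empirical p conservative; the strength
statistic is continuous and is the one whose calibration is checked —
on unstructured random weighted digraphs its false-positive fraction at
0.05 sits near the nominal level. The reference ensemble size in the
original analysis scale is 50,000; the package default is 1,000, which
is ample for z-scores on networks of ~15–20 nodes (the acceptance
checks use 199–500 draws and remain stable across seeds).

## Quality control and markers

Boundary semantics are literal: cells with library size ≤ 2,000 UMIs or
mitochondrial fraction ≥ 5% are excluded (both thresholds exclusionary
at the boundary); genes with nonzero counts in fewer than 3 cells are
removed — exactly-3 survives — with a flag-only mode that marks them
undetected instead of dropping them. Spatial matrices are filtered
spots-first (< 200 detected genes removed), then genes by total count
(< 10) and prevalence (< 3 spots). Mitochondrial genes are recognized
by a configurable name prefix (default `MT-`).

Markers are ranked per cell type one-vs-rest: a two-sided Wilcoxon
rank-sum test per gene on log-normalized expression,
Benjamini–Hochberg adjustment, and a Seurat-style average log
fold-change, log(mean(expm1(x_in)) + 1) − log(mean(expm1(x_out)) + 1)
(natural log — the scale on which the 0.15 threshold is defined). Genes
need adjusted p ≤ 0.05, fold change ≥ 0.15 and positive direction;
ordering is fold change descending with ties broken by adjusted p then
gene name, truncated to the top 30. Types with fewer than 3 cells are
skipped with a warning.

## Signature scoring

*Module score* (per cell): mean signature expression minus the mean of
expression-matched controls. Genes are binned into 24 bins by
dataset-wide average expression; each signature gene contributes up to
100 control genes drawn without replacement from its own bin, seeded.
The score is scale-dependent by construction (documented; the two
rank-based scores below are not).

*AUC recovery score* (per cell): genes are ranked by decreasing
expression, ties broken by a seeded gene shuffle; with
R = ⌈top_frac × n_genes⌉ and h(x) the number of signature genes among
the top x, the score is Σ_x h(x) normalized by the maximum achievable
area, giving [0, 1] with 1 = all signature genes at the very top.

*ssGSEA* (per bulk sample): average ranks of expression within the
sample; walking from the top-ranked gene down, the score accumulates
the difference between the weighted in-set ECDF (weights |rank|^α,
α = 0.25) and the uniform out-of-set ECDF, summed over all positions.
When normalization is on, each signature's scores are divided by their
(max − min) across samples — per-signature range normalization, which
makes each signature's scores comparable across samples on a common
[≈0, 1] span before clustering (a global-range variant used elsewhere
rescales all signatures by one constant; both feed identical rankings
per signature, and the per-signature form is the one the subtyping
stage assumes). Signatures with fewer than 2 matrix genes are skipped
with a warning.

## TME subtyping

Samples are clustered on z-scaled signature scores with Ward-linkage
hierarchical clustering (squared-Euclidean merges, the ward.D2
convention) or k-means (k-means++ with 25 restarts, seeded), sweeping
k = 2..10. The selection criterion is mean silhouette (the reference
analysis says only that the best clustering effect was sought; the
silhouette is the standard explicit choice), with a gap-statistic mode
and a fixed-k mode (to reproduce an interpretation-chosen k). When the
best mean silhouette is below 0.25 the assignment is flagged
weak-structure. Constant score columns are dropped with a warning;
fewer samples than k_max + 1 lowers k_max with a warning.

Semantic labels operationalize the four TME patterns explicitly: per
cluster, a barrier index (mean centroid over barrier signatures) and an
exhaustion index (over exhaustion signatures) are median-split across
clusters; high/high → barrier_with_exhaustion, high/low →
barrier_dominant, low/high → exhaustion_dominant, low/low → desert.
Labels depend only on centroids, so they are invariant to cluster-id
permutations.

## Synthetic data

The generators define the study conditions the tests assume.

*Single-cell counts*: negative binomial with shared dispersion θ
(variance μ + μ²/θ, θ = 2 by default — moderate overdispersion typical
of UMI counts), per-gene baseline means given log-normal spread
(σ = 0.5) so expression bins are non-trivial. Each cell type carries a
block of marker genes elevated 2^marker_log2fc-fold (default 4×);
planted ligand–receptor activity multiplies the ligand mean in the
sender type and the receptor mean in the receiver type by a stated fold
change. A configurable fraction of genes is named with the `MT-` prefix
so QC filters are exercisable. Defaults (4 types × 100 cells × 300
genes) are a deliberately scaled-down cohort: libraries of ~100 counts
rather than thousands, which is why the pipeline demo applies
correspondingly scaled QC depth thresholds while `QCThresholds()`
itself keeps the real-data defaults.

*Weighted digraphs*: exact in/out degree sequences realized by
configuration-model stub matching with swap-based repair of self-loops
and duplicates, randomized by further double-edge swaps. Motif
instances are planted by rewriting the induced subgraph on a fresh node
tuple into the exact target pattern using only degree-preserving double
swaps (pairs already committed to earlier plants are frozen), so the
requested degree sequences survive exactly and the census provably
contains at least the requested instance count. Background weights are
i.i.d. log-normal(−1, 0.5); planted edges are multiplied by a weight
boost. The planted-recovery conditions used in the acceptance checks —
15 nodes with in/out degree 3 (45 arcs, the sparse regime typical of a
pruned communication network), 8 feed-forward loops boosted 5× — were
fixed by a pre-build power characterization and give the feed-forward
class the top strength z-score in ≥ 9/10 replicates at 500 null draws.

*Bulk mixtures*: Gaussian log-scale expression (baseline 5, noise sd 1)
with additive per-subtype shifts on signature genes; a scalar effect e
means subtype g is shifted by e on signature g. True labels are
returned with the matrix. The generator emulates the first-order
structure the subtyping stage relies on — separable signature-mean
shifts — and deliberately omits gene–gene correlation, compositional
mixing, batch effects and heavy-tailed noise; recovery results on it
bound what the clustering can do under clean separation, not what it
will achieve on real cohorts.

None of the generators simulate spatial coordinates, doublets, batch
structure, or trajectories.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng` seeds; a
  global pipeline seed derives per-stage seeds by hashing the stage
  name, so stages never share streams and runs are bit-reproducible
  (manifests record output checksums).
- Ranks use average ties for ssGSEA; the AUC score breaks ties by a
  seeded shuffle; marker p-values use the asymptotic rank-sum with tie
  correction and are set to 1 where the statistic is undefined
  (zero-variance genes).
- Rigid graphs with no valid swap (e.g. a directed 3-cycle) are
  returned unchanged by rewiring and yield degenerate ensembles:
  empirical p = 1, z reported as NaN.
- Empty censuses, empty networks, missing roots, absent signature
  genes, and sub-minimum group sizes raise explicit errors or warnings
  as documented per function.

## Problem sizes

Default test and acceptance workloads are desk-scale: networks of
9–15 nodes, ensembles of 199–500 draws, cohorts of 24–48 samples and
100–400 genes, chosen so the full suite and the acceptance script each
complete in well under a minute of compute per section while leaving
every statistical conclusion (oracle exactness, calibration bands,
planted-effect recovery) stable across seeds. All sizes scale up by
argument.

## Known limitations

- The Hill communication score is a surrogate: absolute strengths are
  not comparable with communication-probability tools, only the induced
  network topology and relative weights are meaningful.
- Induced-subgraph counting means a class's count can drop when edges
  are added (a chain becomes a feed-forward loop); interpret per-class
  trends jointly.
- The rewiring null conditions on degrees and the weight multiset; it
  does not model uncertainty in the strengths themselves.
- Silhouette-based k selection inherits silhouette's bias toward
  compact, balanced clusters; the fixed-k mode exists for externally
  chosen k.
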