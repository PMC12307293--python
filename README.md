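# tmenet

Cell–cell communication networks, directed motif analysis with a
degree-preserving rewiring null, gene-signature scoring, and
tumor-microenvironment (TME) subtyping — as one tested Python package.

## Who this is for

Single-cell and bulk transcriptomics analysts who want to go from a
labeled expression matrix to (1) a weighted directed cell-type
communication network, (2) its hierarchy and its statistically
significant 2–4-node interaction motifs, and (3) signature-score-based
subtypes of bulk cohorts — with every step reproducible, seeded, and
exercisable on synthetic data in which the recoverable effect is
planted by construction.

## The core method

Ligand–receptor communication from sender type *s* to receiver type *r*
is scored with a saturating mass-action form,

    strength(s→r) = L·R / (k_h + L·R),

with L and R trimmed-mean log-normalized ligand/receptor levels
(geometric mean across subunits) and half-saturation k_h = 0.5. Pair
strengths sum into a weighted digraph on cell types. After pruning
edges with weight < 1e-4, the root is the node of highest weighted
outdegree and layers are BFS distances from it.

Every connected induced subgraph on 2–4 nodes is then enumerated and
classified into its directed isomorphism class (canonical adjacency
bit-string; 3-node classes carry standard triad codes — the
feed-forward loop is 030T). Each class is scored by instance count and
by **sum strength** (total edge weight over instances), and both are
tested against an ensemble of degree-preserving rewired networks
(directed double-edge swaps; weights ride with arcs, so every draw
preserves the in/out degree sequences *and* the weight multiset):
z = (obs − mean)/sd and empirical p = (1 + #{null ≥ obs})/(1 + n_random).

On the bulk side, signatures are scored per sample with single-sample
GSEA (weighted running sum, α = 0.25), and samples are clustered on
z-scaled scores (Ward / k-means, k = 2..10, silhouette-selected) into
TME subtypes labeled by a median split of barrier and exhaustion
indices: barrier-dominant, barrier-with-exhaustion, exhaustion-dominant,
or desert. Per-cell scoring (control-bin module score, AUC recovery
score) and the QC/marker stages (library-size/mito filters, one-vs-rest
Wilcoxon markers with BH adjustment and a top-30 rule) round out the
pipeline. See `docs/methods.md` for the full model description.

## Worked example

Plant 8 weight-boosted feed-forward loops in a 15-node degree-3
digraph, then ask the census + null which 3-node pattern concentrates
the most weight:

```python
from tmenet import (SyntheticGraphSpec, gen_weighted_digraph,
                    NullConfig, motif_significance, find_root)

spec = SyntheticGraphSpec(
    n_nodes=15, out_degree_seq=[3] * 15, in_degree_seq=[3] * 15,
    planted_motifs=[("ffl", 8, 5.0)], seed=1,
)
net = gen_weighted_digraph(spec)
print("root:", find_root(net))

stats = motif_significance(net, NullConfig(n_random=500, seed=1), sizes=(3,))
cols = ["alias", "obs_count", "obs_strength", "z_strength", "p_strength"]
print(stats.table[stats.table["size"] == 3]
      .sort_values("z_strength", ascending=False)[cols].head(4).round(3))
```

Output:

```
root: v04
         alias  obs_count  obs_strength  z_strength  p_strength
class_id
3-001011  030T       19.0        93.421       3.796       0.002
3-000110  021C       93.0       256.224       2.232       0.014
3-000011  021D       22.0        63.366       0.703       0.242
3-001010  021U       22.0        63.386       0.669       0.257
```

The feed-forward loop (030T) ranks first by strength z-score with
empirical p = 0.002 at 500 rewired draws: the 8 planted, 5×-boosted
instances concentrate far more weight in that pattern than any
degree-matched rewiring does. The runner-up chain class (021C) is
partially dragged along because every feed-forward loop contains
chains; the z-gap between them is the discriminating signal.

The same flow runs from the shell:

```bash
tmenet synth graph --config graph.yaml --out net.tsv
tmenet motifs census net.tsv --sizes 2,3,4 --out census.tsv
tmenet motifs null net.tsv --n-random 1000 --seed 7 --out null.tsv
tmenet pipeline run --config run.yaml --out results/ --seed 7
```

`tmenet pipeline run` executes the full chain (synthetic single-cell
counts → QC → markers → communication network → hierarchy → motif
census + null → synthetic bulk → ssGSEA → TME subtypes) and writes a
JSON manifest with per-stage status and output checksums.

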