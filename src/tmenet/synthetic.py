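"""Synthetic inputs with planted, recoverable structure.

Three generators cover everything the pipeline consumes:

* multi-cell-type single-cell counts — negative-binomial noise, planted
  per-type marker genes, and planted sender->receiver ligand-receptor
  activity;
* simple weighted digraphs with exact in/out degree sequences and
  planted, weight-boosted motif instances;
* bulk sample-by-gene matrices mixing signature effects across planted
  subtype groups.

All generators are seed-deterministic: the same config yields
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._utils import ConfigError, GenerationError, check_positive
from .motifs import NAMED_MOTIFS, _mask_to_edges, _pair_positions

__all__ = [
    "SyntheticScConfig",
    "SyntheticGraphSpec",
    "SyntheticBulkConfig",
    "gen_sc_expression",
    "gen_weighted_digraph",
    "gen_bulk_mixtures",
]

LABEL_KEY = "cell_type"


# ---------------------------------------------------------------------------
# single-cell counts


@dataclass
class SyntheticScConfig:
    """Negative-binomial single-cell count simulation.

    ``lr_plants`` entries are (ligand gene index, receptor gene index,
    sender type index, receiver type index, fold change); the ligand is
    multiplied by the fold change in the sender type, the receptor in
    the receiver type.
    """

    n_cell_types: int = 4
    cells_per_type: int = 100
    n_genes: int = 300
    n_markers_per_type: int = 10
    marker_log2fc: float = 2.0
    baseline_mean: float = 0.3
    nb_dispersion: float = 2.0
    lr_plants: List[Tuple[int, int, int, int, float]] = field(default_factory=list)
    mito_gene_frac: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cell_types", "cells_per_type", "n_genes"):
            check_positive(name, getattr(self, name))
        if self.n_markers_per_type < 0:
            raise ConfigError("n_markers_per_type must be >= 0")
        check_positive("marker_log2fc", self.marker_log2fc)
        check_positive("baseline_mean", self.baseline_mean)
        check_positive("nb_dispersion", self.nb_dispersion)
        if self.n_markers_per_type * self.n_cell_types > self.n_genes:
            raise ConfigError("marker blocks exceed the number of genes")
        if not 0 <= self.mito_gene_frac < 1:
            raise ConfigError("mito_gene_frac must be in [0, 1)")
        for lig, rec, s, r, fold in self.lr_plants:
            if lig == rec:
                raise ConfigError("planted ligand and receptor must be distinct genes")
            if not (0 <= lig < self.n_genes and 0 <= rec < self.n_genes):
                raise ConfigError("planted gene index out of range")
            if not (0 <= s < self.n_cell_types and 0 <= r < self.n_cell_types):
                raise ConfigError("planted cell-type index out of range")
            if fold < 1:
                raise ConfigError("planted fold change must be >= 1")


def gen_sc_expression(config: SyntheticScConfig) -> ad.AnnData:
    """Simulate labeled single-cell counts with planted structure.

    Marker gene g of type t has mean ``baseline * 2**marker_log2fc`` in
    type t; planted ligand/receptor genes are elevated by their fold
    change in the sender/receiver type. Counts are negative binomial
    with shared dispersion (variance mu + mu^2 / dispersion).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_types, n_genes = config.n_cell_types, config.n_genes
    n_cells = n_types * config.cells_per_type

    # per-gene baseline with lognormal spread so expression bins are nontrivial
    gene_scale = np.exp(rng.normal(0.0, 0.5, size=n_genes))
    base = config.baseline_mean * gene_scale

    mu = np.tile(base, (n_types, 1))  # type x gene mean
    for t in range(n_types):
        lo = t * config.n_markers_per_type
        hi = lo + config.n_markers_per_type
        mu[t, lo:hi] *= 2.0**config.marker_log2fc
    for lig, rec, s, r, fold in config.lr_plants:
        mu[s, lig] *= fold
        mu[r, rec] *= fold

    theta = config.nb_dispersion
    blocks = []
    for t in range(n_types):
        p = theta / (theta + mu[t])
        blocks.append(
            rng.negative_binomial(theta, p, size=(config.cells_per_type, n_genes))
        )
    X = np.vstack(blocks)

    n_mito = int(round(config.mito_gene_frac * n_genes))
    marker_span = n_types * config.n_markers_per_type
    planted = {g for pl in config.lr_plants for g in pl[:2]}
    genes = []
    mito_assigned = 0
    for g in range(n_genes):
        if mito_assigned < n_mito and g >= marker_span and g not in planted:
            genes.append(f"MT-g{g:04d}")
            mito_assigned += 1
        else:
            genes.append(f"g{g:04d}")

    labels = np.repeat([f"ct{t}" for t in range(n_types)], config.cells_per_type)
    obs = pd.DataFrame(
        {LABEL_KEY: pd.Categorical(labels)},
        index=[f"cell{i:05d}" for i in range(n_cells)],
    )
    var = pd.DataFrame(index=genes)
    var["mt"] = [g.startswith("MT-") for g in genes]
    adata = ad.AnnData(X=sp.csr_matrix(X), obs=obs, var=var)
    adata.uns["synthetic"] = {
        "marker_genes": {
            f"ct{t}": [
                genes[g]
                for g in range(
                    t * config.n_markers_per_type, (t + 1) * config.n_markers_per_type
                )
            ]
            for t in range(n_types)
        },
        "lr_plants": [
            (genes[lig], genes[rec], f"ct{s}", f"ct{r}", fold)
            for lig, rec, s, r, fold in config.lr_plants
        ],
    }
    return adata


# ---------------------------------------------------------------------------
# weighted digraphs with planted motifs


@dataclass
class SyntheticGraphSpec:
    """Simple digraph with exact degree sequences and planted motifs.

    ``planted_motifs`` entries are (motif name or class id, count,
    weight boost); names come from :data:`tmenet.motifs.NAMED_MOTIFS`.
    Background weights are i.i.d. log-normal(meanlog, sdlog); planted
    instance edges are multiplied by the boost.
    """

    n_nodes: int = 12
    out_degree_seq: Optional[Sequence[int]] = None
    in_degree_seq: Optional[Sequence[int]] = None
    planted_motifs: List[Tuple[str, int, float]] = field(default_factory=list)
    background_weight_dist: Tuple[float, float] = (-1.0, 0.5)
    seed: int = 0
    max_attempts: int = 2000

    def validate(self) -> None:
        check_positive("n_nodes", self.n_nodes)
        if self.out_degree_seq is None or self.in_degree_seq is None:
            raise ConfigError("both degree sequences are required")
        outs, ins = list(self.out_degree_seq), list(self.in_degree_seq)
        if len(outs) != self.n_nodes or len(ins) != self.n_nodes:
            raise ConfigError("degree sequences must have length n_nodes")
        if any(d < 0 for d in outs + ins):
            raise ConfigError("degrees must be nonnegative")
        if sum(outs) != sum(ins):
            raise ConfigError("sum(out_degree_seq) must equal sum(in_degree_seq)")
        if max(outs + ins, default=0) > self.n_nodes - 1:
            raise ConfigError("degree exceeds n_nodes - 1 (simple digraph)")
        for name, count, boost in self.planted_motifs:
            if count < 0:
                raise ConfigError("planted count must be >= 0")
            check_positive("weight boost", boost)
            _motif_edges(name)  # raises on unknown name


def _motif_edges(name: str) -> List[Tuple[int, int]]:
    if name in NAMED_MOTIFS:
        return list(NAMED_MOTIFS[name])
    if "-" in name:  # class id "k-bits"
        k_str, bits = name.split("-", 1)
        k = int(k_str)
        return _mask_to_edges(int(bits, 2), k)
    raise ConfigError(f"unknown motif {name!r}")


def _realize_degrees(outs, ins, rng, max_attempts=2000):
    """Simple digraph with the exact degree sequences (configuration model).

    Random stub matching, then self-loops and duplicate arcs are repaired
    by degree-preserving head exchanges; each accepted repair strictly
    reduces the number of offending arcs, so the loop terminates. A final
    round of random double-edge swaps removes any residual matching bias.
    """
    from .nullmodel import _rewire_arrays

    n = len(outs)
    src = np.repeat(np.arange(n), outs)
    m = len(src)
    if m == 0:
        return set()
    for _restart in range(max_attempts):
        dst = np.repeat(np.arange(n), ins)[rng.permutation(m)]
        counts: Dict[Tuple[int, int], int] = {}
        for e in zip(src.tolist(), dst.tolist()):
            counts[e] = counts.get(e, 0) + 1

        def bad(i):
            e = (src[i], dst[i])
            return e[0] == e[1] or counts[e] > 1

        bad_idx = [i for i in range(m) if bad(i)]
        budget = 200 * m
        while bad_idx and budget > 0:
            i = bad_idx[-1]
            if not bad(i):
                bad_idx.pop()
                continue
            repaired = False
            for j in rng.integers(0, m, size=50):
                if j == i:
                    continue
                u1, v1 = src[i], dst[i]
                u2, v2 = int(src[j]), int(dst[j])
                if u1 == v2 or u2 == v1:
                    continue
                new1, new2 = (u1, v2), (u2, v1)
                extra = 1 if new1 == new2 else 0
                if counts.get(new1, 0) + extra > 0 or counts.get(new2, 0) > 0:
                    continue
                for e in ((u1, v1), (u2, v2)):
                    counts[e] -= 1
                    if counts[e] == 0:
                        del counts[e]
                counts[new1] = counts.get(new1, 0) + 1
                counts[new2] = counts.get(new2, 0) + 1
                dst[i], dst[j] = v2, v1
                repaired = True
                break
            budget -= 1
            if not repaired:
                break  # restart with a fresh matching
            bad_idx = [k for k in bad_idx if bad(k)]
        if not bad_idx:
            _rewire_arrays(src, dst, 10 * m, rng, n)  # heads only change
            return set(zip(src.tolist(), dst.tolist()))
    raise GenerationError(
        "degree sequence not realized as a simple digraph within attempt budget"
    )


def _targeted_add(edges, u, v, forbidden_nodes, frozen, rng):
    """Create arc (u, v) by one degree-preserving double swap.

    Removes some (u, x) and (y, v) and adds (u, v) and (y, x), with x, y
    outside the working node tuple and no frozen pair touched. Returns
    the new edge set or None.
    """
    ux = [
        (a, b)
        for (a, b) in edges
        if a == u and b != v and b not in forbidden_nodes and (a, b) not in frozen
    ]
    yv = [
        (a, b)
        for (a, b) in edges
        if b == v and a != u and a not in forbidden_nodes and (a, b) not in frozen
    ]
    rng.shuffle(ux)
    rng.shuffle(yv)
    for (_, x) in ux:
        for (y, _) in yv:
            if y == x or (y, x) in edges or (y, x) in frozen:
                continue
            new = set(edges)
            new.discard((u, x))
            new.discard((y, v))
            new.add((u, v))
            new.add((y, x))
            return new
    return None


def _targeted_remove(edges, a, b, forbidden_nodes, frozen, rng):
    """Delete arc (a, b) by one degree-preserving double swap."""
    partners = [
        (c, d)
        for (c, d) in edges
        if c not in forbidden_nodes
        and d not in forbidden_nodes
        and (c, d) != (a, b)
        and (c, d) not in frozen
    ]
    rng.shuffle(partners)
    for (c, d) in partners:
        if a == d or c == b:
            continue
        if (a, d) in edges or (c, b) in edges:
            continue
        if (a, d) in frozen or (c, b) in frozen:
            continue
        new = set(edges)
        new.discard((a, b))
        new.discard((c, d))
        new.add((a, d))
        new.add((c, b))
        return new
    return None


def gen_weighted_digraph(spec: SyntheticGraphSpec) -> nx.DiGraph:
    """Realize the degree sequences exactly and plant boosted motifs.

    Planting rewrites the induced subgraph on a fresh node tuple into the
    exact motif pattern using degree-preserving double swaps only, so the
    requested in/out degree sequences survive unchanged.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    outs = np.asarray(spec.out_degree_seq, dtype=int)
    ins = np.asarray(spec.in_degree_seq, dtype=int)
    edges = _realize_degrees(outs, ins, rng)

    frozen: Dict[Tuple[int, int], bool] = {}
    planted_edges: List[Tuple[Tuple[int, int], float]] = []
    used_tuples = set()
    for name, count, boost in spec.planted_motifs:
        pattern = _motif_edges(name)
        k = max(max(e) for e in pattern) + 1
        want = set(pattern)
        for _ in range(count):
            success = False
            for _attempt in range(spec.max_attempts):
                nodes = tuple(rng.choice(spec.n_nodes, size=k, replace=False))
                if frozenset(nodes) in used_tuples:
                    continue
                desired = {}
                ok = True
                for (i, j) in _pair_positions(k):
                    pair = (nodes[i], nodes[j])
                    state = (i, j) in want
                    if pair in frozen and frozen[pair] != state:
                        ok = False
                        break
                    desired[pair] = state
                if not ok:
                    continue
                work = set(edges)
                node_set = set(nodes)
                for pair, state in desired.items():
                    if state and pair not in work:
                        work = _targeted_add(work, *pair, node_set, frozen, rng)
                    elif not state and pair in work:
                        work = _targeted_remove(work, *pair, node_set, frozen, rng)
                    if work is None:
                        break
                if work is None:
                    continue
                edges = work
                frozen.update(desired)
                used_tuples.add(frozenset(nodes))
                for (i, j) in pattern:
                    planted_edges.append(((nodes[i], nodes[j]), boost))
                success = True
                break
            if not success:
                raise GenerationError(
                    f"could not plant motif {name!r} within attempt budget"
                )

    meanlog, sdlog = spec.background_weight_dist
    width = len(str(spec.n_nodes - 1))
    net = nx.DiGraph()
    net.add_nodes_from(f"v{i:0{width}d}" for i in range(spec.n_nodes))
    weights = {e: float(rng.lognormal(meanlog, sdlog)) for e in sorted(edges)}
    for (pair, boost) in planted_edges:
        weights[pair] *= boost
    for (u, v), w in weights.items():
        net.add_edge(f"v{u:0{width}d}", f"v{v:0{width}d}", weight=w)
    return net


# ---------------------------------------------------------------------------
# bulk mixtures


@dataclass
class SyntheticBulkConfig:
    """Bulk sample-by-gene matrices with planted subtype structure.

    ``group_effect`` is a (k_true x n_signatures) array of additive mean
    shifts on signature genes, or a scalar e meaning subtype g is shifted
    by e on signature g (requires k_true == number of signatures). When
    ``group_assignments`` is None, samples are assigned round-robin.
    """

    n_samples: int = 48
    n_genes: int = 400
    signatures: Dict[str, List[int]] = field(default_factory=dict)
    k_true: int = 4
    group_assignments: Optional[Sequence[int]] = None
    group_effect: Union[float, np.ndarray] = 3.0
    noise_sd: float = 1.0
    baseline: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        check_positive("n_samples", self.n_samples)
        check_positive("n_genes", self.n_genes)
        check_positive("noise_sd", self.noise_sd)
        if self.k_true < 2:
            raise ConfigError("k_true must be >= 2")
        if not self.signatures:
            raise ConfigError("at least one signature is required")
        for name, genes in self.signatures.items():
            if len(genes) == 0:
                raise ConfigError(f"signature {name!r} is empty")
            if max(genes) >= self.n_genes or min(genes) < 0:
                raise ConfigError(f"signature {name!r} gene index out of range")
        if self.group_assignments is not None:
            ga = list(self.group_assignments)
            if len(ga) != self.n_samples:
                raise ConfigError("group_assignments length must equal n_samples")
            if not set(ga) <= set(range(self.k_true)):
                raise ConfigError("group_assignments must be in 0..k_true-1")
        if np.isscalar(self.group_effect):
            if self.k_true != len(self.signatures):
                raise ConfigError(
                    "scalar group_effect requires k_true == number of signatures"
                )
        else:
            eff = np.asarray(self.group_effect, dtype=float)
            if eff.shape != (self.k_true, len(self.signatures)):
                raise ConfigError("group_effect must be (k_true, n_signatures)")


def gen_bulk_mixtures(config: SyntheticBulkConfig) -> ad.AnnData:
    """Gaussian log-scale bulk expression with additive subtype effects.

    Signature-gene means differ across subtypes by ``group_effect``; all
    other genes are exchangeable noise. True labels are in
    ``obs["subtype"]`` and gene-name signatures in ``uns["signatures"]``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sig_names = list(config.signatures)
    if np.isscalar(config.group_effect):
        eff = np.eye(config.k_true) * float(config.group_effect)
    else:
        eff = np.asarray(config.group_effect, dtype=float)
    if config.group_assignments is None:
        groups = np.arange(config.n_samples) % config.k_true
    else:
        groups = np.asarray(list(config.group_assignments), dtype=int)

    X = config.baseline + rng.normal(
        0.0, config.noise_sd, size=(config.n_samples, config.n_genes)
    )
    for j, name in enumerate(sig_names):
        genes = np.asarray(config.signatures[name], dtype=int)
        for g in range(config.k_true):
            rows = np.nonzero(groups == g)[0]
            X[np.ix_(rows, genes)] += eff[g, j]

    gene_names = [f"g{i:04d}" for i in range(config.n_genes)]
    obs = pd.DataFrame(
        {"subtype": pd.Categorical([f"S{g + 1}" for g in groups])},
        index=[f"sample{i:03d}" for i in range(config.n_samples)],
    )
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=gene_names))
    adata.uns["signatures"] = {
        name: [gene_names[g] for g in config.signatures[name]] for name in sig_names
    }
    return adata
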