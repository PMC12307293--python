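"""Directed motif census for 2-, 3- and 4-node connected subgraphs.

Every induced, weakly-connected subgraph on k nodes of a simple weighted
digraph is counted exactly once per node set, classified into its directed
isomorphism class, and scored by the sum of its induced edge weights (the
"sum strength" motif statistic). Classes are identified by the
lexicographically minimal adjacency bit-string over all k! relabelings —
exhaustive canonicalization, which is exact and cheap for k <= 4.

The enumeration is vectorized over node subsets so that the same census
can be re-run thousands of times inside the rewiring null ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("tmenet")

SUPPORTED_SIZES = (2, 3, 4)

#: Edge lists (on nodes 0..k-1) for motif shapes with standard names.
NAMED_MOTIFS: Dict[str, List[Tuple[int, int]]] = {
    "arc": [(0, 1)],
    "mutual": [(0, 1), (1, 0)],
    "chain3": [(0, 1), (1, 2)],
    "fan_out": [(0, 1), (0, 2)],
    "fan_in": [(0, 2), (1, 2)],
    "ffl": [(0, 1), (0, 2), (1, 2)],  # feed-forward loop
    "cycle3": [(0, 1), (1, 2), (2, 0)],
    "cycle4": [(0, 1), (1, 2), (2, 3), (3, 0)],
    "bifan": [(0, 2), (0, 3), (1, 2), (1, 3)],
}


@dataclass(frozen=True)
class MotifClass:
    """A directed isomorphism class of a small digraph."""

    size: int
    class_id: str
    alias: Optional[str] = None


@dataclass
class MotifCensus:
    """Per-class instance counts and summed edge-weight strengths.

    ``table`` has one row per weakly-connected isomorphism class of each
    requested size (zero-count classes included so ensembles align),
    indexed by class id with columns size, alias, count, total_strength.
    """

    table: pd.DataFrame
    instances: Optional[pd.DataFrame] = None
    sizes: Tuple[int, ...] = field(default_factory=tuple)

    def top(self, n: int) -> pd.DataFrame:
        return top_motifs(self, n)


# ---------------------------------------------------------------------------
# canonicalization tables


def _pair_positions(k: int) -> List[Tuple[int, int]]:
    """Ordered node pairs (i, j), i != j, in bit-position order."""
    return [(i, j) for i in range(k) for j in range(k) if i != j]


@lru_cache(maxsize=None)
def _tables(k: int):
    """Canonical-form and connectivity lookup tables for all k-node digraphs.

    Returns (canon, class_index, connected_ids, class_ids_all) where
    ``canon[mask]`` is the canonical mask, ``class_index[mask]`` indexes
    into ``connected_ids`` (-1 for disconnected classes) and
    ``connected_ids`` lists canonical masks of weakly-connected classes.
    """
    if k not in SUPPORTED_SIZES:
        raise ValueError(f"unsupported motif size {k}; supported: {SUPPORTED_SIZES}")
    pairs = _pair_positions(k)
    nbits = len(pairs)
    pos = {p: i for i, p in enumerate(pairs)}
    masks = np.arange(1 << nbits, dtype=np.int64)
    bits = (masks[:, None] >> np.arange(nbits)[None, :]) & 1  # (2^nbits, nbits)

    canon = masks.copy()
    for perm in permutations(range(k)):
        # relabeled graph has edge (a,b) iff original has (perm[a],perm[b])
        src = np.array([pos[(perm[a], perm[b])] for (a, b) in pairs])
        remapped = (bits[:, src] << np.arange(nbits)[None, :]).sum(axis=1)
        canon = np.minimum(canon, remapped)

    def _connected(mask: int) -> bool:
        parent = list(range(k))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for b, (i, j) in enumerate(pairs):
            if (mask >> b) & 1:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
        return len({find(i) for i in range(k)}) == 1

    class_masks_all = np.unique(canon)
    connected_ids = np.array(
        [m for m in class_masks_all if _connected(int(m))], dtype=np.int64
    )
    class_index = np.full(1 << nbits, -1, dtype=np.int64)
    lookup = {int(m): i for i, m in enumerate(connected_ids)}
    for mask in range(1 << nbits):
        idx = lookup.get(int(canon[mask]))
        if idx is not None:
            class_index[mask] = idx
    return canon, class_index, connected_ids, class_masks_all


def _mask_to_edges(mask: int, k: int) -> List[Tuple[int, int]]:
    return [(i, j) for b, (i, j) in enumerate(_pair_positions(k)) if (mask >> b) & 1]


def _edges_to_mask(edges: Iterable[Tuple[int, int]], k: int) -> int:
    pos = {p: i for i, p in enumerate(_pair_positions(k))}
    mask = 0
    for e in edges:
        mask |= 1 << pos[tuple(e)]
    return mask


def _class_id(k: int, canon_mask: int) -> str:
    nbits = k * (k - 1)
    return f"{k}-{canon_mask:0{nbits}b}"


@lru_cache(maxsize=None)
def _alias_table(k: int) -> Dict[str, str]:
    """Human aliases: triad-census codes for size 3, named shapes otherwise."""
    aliases: Dict[str, str] = {}
    canon, _, connected_ids, _ = _tables(k)
    if k == 3:
        for m in connected_ids:
            g = nx.DiGraph(_mask_to_edges(int(m), 3))
            g.add_nodes_from(range(3))
            aliases[_class_id(3, int(m))] = nx.triad_type(g)
    for name, edges in NAMED_MOTIFS.items():
        size = max(max(e) for e in edges) + 1
        if size == k:
            cid = _class_id(k, int(canon[_edges_to_mask(edges, k)]))
            aliases.setdefault(cid, name)
    return aliases


def canonical_class(adj: np.ndarray) -> MotifClass:
    """Classify a small adjacency matrix into its isomorphism class.

    ``adj`` is a k x k 0/1 matrix, k <= 4; the diagonal is ignored.
    """
    adj = np.asarray(adj)
    k = adj.shape[0]
    if k not in SUPPORTED_SIZES:
        raise ValueError(f"unsupported motif size {k}; supported: {SUPPORTED_SIZES}")
    canon, _, _, _ = _tables(k)
    mask = _edges_to_mask(
        [(i, j) for i in range(k) for j in range(k) if i != j and adj[i, j]], k
    )
    cid = _class_id(k, int(canon[mask]))
    return MotifClass(size=k, class_id=cid, alias=_alias_table(k).get(cid))


def named_motif_class(name: str) -> MotifClass:
    """Resolve a named motif shape (e.g. ``"ffl"``) to its class."""
    edges = NAMED_MOTIFS[name]
    k = max(max(e) for e in edges) + 1
    adj = np.zeros((k, k), dtype=int)
    for i, j in edges:
        adj[i, j] = 1
    return canonical_class(adj)


def connected_classes(k: int) -> List[MotifClass]:
    """All weakly-connected isomorphism classes of k-node digraphs."""
    _, _, connected_ids, _ = _tables(k)
    alias = _alias_table(k)
    out = []
    for m in connected_ids:
        cid = _class_id(k, int(m))
        out.append(MotifClass(size=k, class_id=cid, alias=alias.get(cid)))
    return out


# ---------------------------------------------------------------------------
# enumeration


@lru_cache(maxsize=64)
def _subsets(n: int, k: int) -> np.ndarray:
    return np.array(list(combinations(range(n), k)), dtype=np.int64).reshape(-1, k)


def _graph_matrices(net: nx.DiGraph):
    nodes = sorted(net.nodes, key=str)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n), dtype=bool)
    W = np.zeros((n, n), dtype=float)
    n_loops = 0
    for u, v, d in net.edges(data=True):
        if u == v:
            n_loops += 1
            continue
        A[index[u], index[v]] = True
        W[index[u], index[v]] = d.get("weight", 1.0)
    if n_loops:
        logger.info("excluding %d self-loop(s) from the motif census", n_loops)
    return nodes, A, W


def _census_arrays(A: np.ndarray, W: np.ndarray, k: int):
    """Counts and total strengths over all connected k-node classes.

    Vectorized over node subsets; returns (counts, strengths, masks, subs)
    where masks/subs allow instance recovery.
    """
    _, class_index, connected_ids, _ = _tables(k)
    n = A.shape[0]
    n_classes = len(connected_ids)
    if n < k:
        z = np.zeros(n_classes)
        return z.astype(np.int64), z, None, None
    subs = _subsets(n, k)
    pairs = _pair_positions(k)
    masks = np.zeros(len(subs), dtype=np.int64)
    strengths = np.zeros(len(subs), dtype=float)
    for b, (i, j) in enumerate(pairs):
        rows, cols = subs[:, i], subs[:, j]
        masks |= A[rows, cols].astype(np.int64) << b
        strengths += W[rows, cols]
    idx = class_index[masks]
    keep = idx >= 0
    counts = np.bincount(idx[keep], minlength=n_classes)
    totals = np.bincount(idx[keep], weights=strengths[keep], minlength=n_classes)
    return counts, totals, masks, subs


def enumerate_motifs(
    net: nx.DiGraph,
    sizes: Sequence[int] = (2, 3, 4),
    keep_instances: bool = False,
    max_instances: int = 100_000,
) -> MotifCensus:
    """Census of connected induced subgraphs of the given sizes.

    Each node set is counted once; the induced subgraph (all arcs among
    the chosen nodes) determines the class, and its strength is the sum
    of induced edge weights.
    """
    sizes = tuple(sorted(set(int(s) for s in sizes)))
    for s in sizes:
        if s not in SUPPORTED_SIZES:
            raise ValueError(f"size {s} outside supported sizes {SUPPORTED_SIZES}")
    nodes, A, W = _graph_matrices(net)
    rows = []
    inst_rows = []
    for k in sizes:
        counts, totals, masks, subs = _census_arrays(A, W, k)
        alias = _alias_table(k)
        _, class_index, connected_ids, _ = _tables(k)
        for i, m in enumerate(connected_ids):
            cid = _class_id(k, int(m))
            rows.append(
                {
                    "class_id": cid,
                    "size": k,
                    "alias": alias.get(cid),
                    "count": int(counts[i]),
                    "total_strength": float(totals[i]),
                }
            )
        if keep_instances and masks is not None:
            idx = class_index[masks]
            for row_i in np.nonzero(idx >= 0)[0]:
                if len(inst_rows) >= max_instances:
                    break
                canon_m = connected_ids[idx[row_i]]
                strength = sum(
                    W[subs[row_i, i], subs[row_i, j]] for (i, j) in _pair_positions(k)
                )
                inst_rows.append(
                    {
                        "class_id": _class_id(k, int(canon_m)),
                        "nodes": ",".join(str(nodes[x]) for x in subs[row_i]),
                        "strength": float(strength),
                    }
                )
    table = pd.DataFrame(rows).set_index("class_id")
    instances = pd.DataFrame(inst_rows) if keep_instances else None
    return MotifCensus(table=table, instances=instances, sizes=sizes)


def top_motifs(census: MotifCensus, n: int) -> pd.DataFrame:
    """Rank observed classes by total strength (ties: count, then class id)."""
    present = census.table[census.table["count"] > 0].copy()
    present = present.sort_values(
        by=["total_strength", "count"], ascending=[False, False], kind="mergesort"
    )
    # stable final tie-break on class id
    present["_cid"] = present.index
    present = present.sort_values(
        by=["total_strength", "count", "_cid"],
        ascending=[False, False, True],
        kind="mergesort",
    ).drop(columns="_cid")
    return present.head(n)
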