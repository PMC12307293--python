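"""Degree-preserving rewiring null ensemble for motif significance.

The null randomizes which node pairs are connected while holding every
node's in- and out-degree fixed, by repeated directed double-edge swaps:
(u1->v1, u2->v2) becomes (u1->v2, u2->v1), rejecting any swap that would
create a self-loop or a duplicate arc. Edge weights ride with their
(tail, weight) arc, so each null draw preserves the weight multiset as
well; an alternative mode re-shuffles weights over arcs independently.

Per-motif-class significance compares the observed count and sum-strength
statistics with their distribution over the ensemble (z-score and
add-one-smoothed empirical tail p).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from ._utils import ConfigError, logger
from .motifs import MotifCensus, _alias_table, _census_arrays, _class_id, _graph_matrices, _tables


@dataclass
class NullConfig:
    """Ensemble parameters.

    n_random=50_000 matches the original analysis scale; 1_000 is a
    practical desk-scale default with stable z-scores on small networks.
    """

    n_random: int = 1000
    swaps_per_edge: float = 10.0
    seed: int = 0
    statistic: str = "both"  # count | strength | both
    weight_mode: str = "ride"  # ride | shuffle
    tail: str = "upper"  # upper | two-sided

    def __post_init__(self):
        if self.n_random < 1:
            raise ConfigError(f"n_random must be >= 1, got {self.n_random}")
        if self.swaps_per_edge <= 0:
            raise ConfigError("swaps_per_edge must be positive")
        if self.statistic not in ("count", "strength", "both"):
            raise ConfigError(f"unknown statistic {self.statistic!r}")
        if self.weight_mode not in ("ride", "shuffle"):
            raise ConfigError(f"unknown weight_mode {self.weight_mode!r}")
        if self.tail not in ("upper", "two-sided"):
            raise ConfigError(f"unknown tail {self.tail!r}")


@dataclass
class NullEnsembleStats:
    """Observed vs null summaries per motif class."""

    table: pd.DataFrame
    n_random: int
    sizes: Tuple[int, ...] = field(default_factory=tuple)


def _rewire_arrays(
    src: np.ndarray,
    dst: np.ndarray,
    n_attempts: int,
    rng: np.random.Generator,
    n_nodes: int,
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Double-edge-swap the arc arrays in place; returns accepted count.

    Arc identity (index) is preserved: arc e keeps its tail and weight,
    only heads are exchanged between the two chosen arcs.
    """
    m = len(src)
    present = set(zip(src.tolist(), dst.tolist()))
    if m < 2:
        return src, dst, 0
    pick = rng.integers(0, m, size=(n_attempts, 2))
    accepted = 0
    for e1, e2 in pick:
        if e1 == e2:
            continue
        u1, v1 = src[e1], dst[e1]
        u2, v2 = src[e2], dst[e2]
        if v1 == v2 or u1 == u2:
            continue  # swap would be a no-op or recreate the same arcs
        if u1 == v2 or u2 == v1:
            continue  # would create a self-loop
        if (u1, v2) in present or (u2, v1) in present:
            continue  # would create a duplicate arc
        present.discard((u1, v1))
        present.discard((u2, v2))
        present.add((u1, v2))
        present.add((u2, v1))
        dst[e1] = v2
        dst[e2] = v1
        accepted += 1
    return src, dst, accepted


def rewire(
    net: nx.DiGraph,
    config: Optional[NullConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> nx.DiGraph:
    """One degree-preserving randomization of a simple digraph."""
    config = config or NullConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    nodes, A, W = _graph_matrices(net)
    src, dst = np.nonzero(A)
    weights = W[src, dst]
    src, dst = src.copy(), dst.copy()
    n_attempts = int(np.ceil(config.swaps_per_edge * len(src)))
    _, _, accepted = _rewire_arrays(src, dst, n_attempts, rng, len(nodes))
    if accepted == 0:
        logger.info("no valid swap found; returning graph unchanged")
    if config.weight_mode == "shuffle":
        weights = weights[rng.permutation(len(weights))]
    out = nx.DiGraph()
    out.add_nodes_from(nodes)
    for u, v, w in zip(src, dst, weights):
        out.add_edge(nodes[u], nodes[v], weight=float(w))
    return out


def motif_significance(
    net: nx.DiGraph,
    config: Optional[NullConfig] = None,
    sizes: Sequence[int] = (2, 3),
) -> NullEnsembleStats:
    """Observed vs rewired-ensemble motif statistics.

    Each of the ``n_random`` null networks is rewired independently from
    the observed graph. For every connected class: z = (obs - mean)/sd
    (sample sd; reported as NaN when sd = 0) and empirical
    p = (1 + #{null >= obs}) / (1 + n_random), upper tail by default.
    """
    config = config or NullConfig()
    sizes = tuple(sorted(set(int(s) for s in sizes)))
    rng = np.random.default_rng(config.seed)
    nodes, A, W = _graph_matrices(net)
    src0, dst0 = np.nonzero(A)
    weights0 = W[src0, dst0]
    n = len(nodes)
    n_attempts = int(np.ceil(config.swaps_per_edge * len(src0)))

    obs_counts, obs_strengths = {}, {}
    for k in sizes:
        c, s, _, _ = _census_arrays(A, W, k)
        obs_counts[k], obs_strengths[k] = c, s

    null_counts = {k: np.empty((config.n_random, len(obs_counts[k]))) for k in sizes}
    null_strengths = {k: np.empty_like(null_counts[k]) for k in sizes}
    An = np.zeros_like(A)
    Wn = np.zeros_like(W)
    for r in range(config.n_random):
        src, dst = src0.copy(), dst0.copy()
        _rewire_arrays(src, dst, n_attempts, rng, n)
        w = weights0
        if config.weight_mode == "shuffle":
            w = weights0[rng.permutation(len(weights0))]
        An[:] = False
        Wn[:] = 0.0
        An[src, dst] = True
        Wn[src, dst] = w
        for k in sizes:
            c, s, _, _ = _census_arrays(An, Wn, k)
            null_counts[k][r] = c
            null_strengths[k][r] = s

    rows = []
    for k in sizes:
        _, _, connected_ids, _ = _tables(k)
        alias = _alias_table(k)
        for i, m in enumerate(connected_ids):
            cid = _class_id(k, int(m))
            row = {"class_id": cid, "size": k, "alias": alias.get(cid)}
            for stat, obs, nulls in (
                ("count", obs_counts[k][i], null_counts[k][:, i]),
                ("strength", obs_strengths[k][i], null_strengths[k][:, i]),
            ):
                if config.statistic not in (stat, "both"):
                    continue
                mean = float(nulls.mean())
                sd = float(nulls.std(ddof=1)) if config.n_random > 1 else 0.0
                z = (float(obs) - mean) / sd if sd > 0 else np.nan
                if config.tail == "upper":
                    extreme = int(np.sum(nulls >= obs))
                else:
                    extreme = int(np.sum(np.abs(nulls - mean) >= abs(obs - mean)))
                p = (1 + extreme) / (1 + config.n_random)
                row.update(
                    {
                        f"obs_{stat}": float(obs),
                        f"null_mean_{stat}": mean,
                        f"null_sd_{stat}": sd,
                        f"z_{stat}": z,
                        f"p_{stat}": p,
                    }
                )
            rows.append(row)
    table = pd.DataFrame(rows).set_index("class_id")
    return NullEnsembleStats(table=table, n_random=config.n_random, sizes=sizes)
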