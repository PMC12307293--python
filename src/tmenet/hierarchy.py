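"""Network pruning, root selection and hierarchical layering.

The communication network is pruned of weak edges (strictly below the
threshold, default 1e-4), the root is the node with the highest weighted
outdegree (lexicographic tie-break), and layers are breadth-first
distances from the root following edge direction; nodes unreachable from
the root are listed separately. A longest-path layering is available for
acyclic networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import networkx as nx

__all__ = ["HierarchyLayout", "prune_edges", "find_root", "layer_nodes"]


@dataclass
class HierarchyLayout:
    root: str
    layers: Dict[str, int]
    unreachable: List[str] = field(default_factory=list)
    min_weight: float = 0.0

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "layers": dict(self.layers),
            "unreachable": list(self.unreachable),
            "min_weight": self.min_weight,
        }


def prune_edges(net: nx.DiGraph, min_weight: float = 1e-4) -> nx.DiGraph:
    """Drop edges with weight strictly below ``min_weight``; keep all nodes."""
    out = nx.DiGraph()
    out.add_nodes_from(net.nodes(data=True))
    for u, v, d in net.edges(data=True):
        if d.get("weight", 1.0) >= min_weight:
            out.add_edge(u, v, **d)
    out.graph.update(net.graph)
    out.graph["min_weight"] = min_weight
    return out


def find_root(net: nx.DiGraph) -> str:
    """Node with the highest weighted outdegree; ties break lexicographically."""
    if net.number_of_nodes() == 0:
        raise ValueError("cannot select a root in an empty network")
    strengths = {
        n: sum(d.get("weight", 1.0) for _, _, d in net.out_edges(n, data=True))
        for n in net.nodes
    }
    return min(strengths, key=lambda n: (-strengths[n], str(n)))


def layer_nodes(
    net: nx.DiGraph, root: str, method: str = "bfs"
) -> HierarchyLayout:
    """Assign layers from the root following edge direction.

    ``method="bfs"`` uses shortest-path distance; ``method="longest_path"``
    uses the longest directed path from the root (acyclic reachable part
    only).
    """
    if root not in net:
        raise ValueError(f"root {root!r} not in network")
    if method == "bfs":
        layers = dict(nx.single_source_shortest_path_length(net, root))
    elif method == "longest_path":
        reachable = set(nx.descendants(net, root)) | {root}
        sub = net.subgraph(reachable)
        if not nx.is_directed_acyclic_graph(sub):
            raise ValueError("longest-path layering requires an acyclic network")
        layers = {root: 0}
        for n in nx.topological_sort(sub):
            for _, v in sub.out_edges(n):
                layers[v] = max(layers.get(v, 0), layers[n] + 1)
    else:
        raise ValueError(f"unknown layering method {method!r}")
    unreachable = sorted(set(map(str, net.nodes)) - set(map(str, layers)), key=str)
    return HierarchyLayout(
        root=str(root),
        layers={str(k): int(v) for k, v in layers.items()},
        unreachable=unreachable,
        min_weight=float(net.graph.get("min_weight", 0.0)),
    )
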