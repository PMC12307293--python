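"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: subgraphs are
enumerated with itertools, isomorphism classes are canonicalized as the
minimum sorted-edge-tuple over all node relabelings, connectivity goes
through networkx, and the ssGSEA running sum is traced gene by gene.
"""

from itertools import combinations, permutations

import networkx as nx
import numpy as np


def canon_edges(edges, k):
    """Canonical form: lexicographically minimal sorted edge tuple over relabelings."""
    best = None
    for perm in permutations(range(k)):
        relabeled = tuple(sorted((perm[u], perm[v]) for (u, v) in edges))
        if best is None or relabeled < best:
            best = relabeled
    return best


def brute_census(net: nx.DiGraph, sizes):
    """All-subsets census: {(k, canonical edge tuple): [count, strength]}."""
    nodes = list(net.nodes)
    out = {}
    for k in sizes:
        for subset in combinations(nodes, k):
            idx = {v: i for i, v in enumerate(subset)}
            sub = net.subgraph(subset)
            edges = [
                (idx[u], idx[v]) for u, v in sub.edges() if u != v
            ]
            if not edges:
                continue
            und = nx.Graph()
            und.add_nodes_from(range(k))
            und.add_edges_from(edges)
            if not nx.is_connected(und):
                continue
            key = (k, canon_edges(edges, k))
            strength = sum(
                d.get("weight", 1.0) for u, v, d in sub.edges(data=True) if u != v
            )
            if key not in out:
                out[key] = [0, 0.0]
            out[key][0] += 1
            out[key][1] += strength
    return out


def class_id_to_oracle_key(class_id: str):
    """Decode a package class id ("k-bits") into the oracle's canonical key."""
    k_str, bits = class_id.split("-", 1)
    k = int(k_str)
    pairs = [(i, j) for i in range(k) for j in range(k) if i != j]
    mask = int(bits, 2)
    edges = [pairs[b] for b in range(len(pairs)) if (mask >> b) & 1]
    return (k, canon_edges(edges, k))


def ssgsea_oracle(values, in_set, alpha):
    """Hand-traced single-sample running sum for one sample.

    ``values`` is the expression vector, ``in_set`` a boolean mask.
    Average ranks, walk genes from highest rank down, accumulate the
    weighted in-set ECDF minus the uniform out-of-set ECDF.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    # average ranks, ascending (top gene gets rank n)
    order = np.argsort(values)
    ranks = np.empty(n)
    i = 0
    sorted_vals = values[order]
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1

    walk = sorted(range(n), key=lambda g: -ranks[g])
    denom_in = sum(abs(ranks[g]) ** alpha for g in walk if in_set[g])
    n_out = sum(1 for g in walk if not in_set[g])
    score = 0.0
    cum_in = 0.0
    cum_out = 0
    for g in walk:
        if in_set[g]:
            cum_in += abs(ranks[g]) ** alpha
        else:
            cum_out += 1
        score += cum_in / denom_in - cum_out / n_out
    return score


def auc_recovery_oracle(ranking, sig_genes, top_n):
    """Step-function integration of the recovery curve.

    ``ranking`` is the gene order from best to worst; h(x) = number of
    signature genes among the top x; returns sum_x h(x) / max area.
    """
    sig = set(sig_genes)
    hits = 0
    area = 0
    for x in range(1, top_n + 1):
        if ranking[x - 1] in sig:
            hits += 1
        area += hits
    m = min(len(sig), top_n)
    max_area = sum(min(x, m) for x in range(1, top_n + 1))
    return area / max_area
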