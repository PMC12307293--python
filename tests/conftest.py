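import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
import pytest


def make_adata(X, labels=None, genes=None):
    """AnnData from a dense array with optional cell-type labels."""
    X = np.asarray(X)
    n_obs, n_var = X.shape
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n_obs)])
    if labels is not None:
        obs["cell_type"] = pd.Categorical(list(labels))
    var = pd.DataFrame(index=genes or [f"g{j}" for j in range(n_var)])
    return ad.AnnData(X=X.astype(float), obs=obs, var=var)


def random_weighted_digraph(n, p, rng):
    """ER digraph with log-normal weights (test helper, not the package)."""
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in range(n):
            if u != v and rng.random() < p:
                g.add_edge(u, v, weight=float(rng.lognormal(-1, 0.5)))
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def three_cycle():
    g = nx.DiGraph()
    g.add_weighted_edges_from([("A", "B", 0.1), ("B", "C", 0.2), ("C", "A", 0.3)])
    return g
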