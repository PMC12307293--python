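"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression travels as Matrix Market triplets plus gene/barcode/label TSVs,
gene sets as GMT, networks as three-column edge-list TSVs, and score
matrices as plain TSV tables.
"""

from __future__ import annotations

import os
from typing import Dict, List

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "write_expression",
    "read_expression",
    "write_gmt",
    "read_gmt",
    "write_edgelist",
    "read_edgelist",
    "write_scores",
    "read_scores",
]

LABEL_KEY = "cell_type"


def write_expression(adata: ad.AnnData, outdir: str) -> None:
    """Write an AnnData as matrix.mtx + genes.tsv + barcodes.tsv + labels.tsv.

    The matrix is stored genes x cells (the conventional MTX orientation)
    even though AnnData is cells x genes.
    """
    os.makedirs(outdir, exist_ok=True)
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), X.T.tocoo())
    pd.Series(adata.var_names).to_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    if LABEL_KEY in adata.obs:
        adata.obs[[LABEL_KEY]].to_csv(
            os.path.join(outdir, "labels.tsv"), sep="\t", header=True
        )


def read_expression(indir: str) -> ad.AnnData:
    """Read the MTX + TSV bundle written by :func:`write_expression`."""
    X = scipy.io.mmread(os.path.join(indir, "matrix.mtx")).T.tocsr()
    genes = pd.read_csv(
        os.path.join(indir, "genes.tsv"), sep="\t", header=None
    )[0].astype(str)
    barcodes = pd.read_csv(
        os.path.join(indir, "barcodes.tsv"), sep="\t", header=None
    )[0].astype(str)
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=barcodes.values),
        var=pd.DataFrame(index=genes.values),
    )
    labels_path = os.path.join(indir, "labels.tsv")
    if os.path.exists(labels_path):
        labels = pd.read_csv(labels_path, sep="\t", index_col=0)
        adata.obs[LABEL_KEY] = labels[LABEL_KEY].reindex(adata.obs_names).values
    return adata


def write_gmt(sets: Dict[str, List[str]], path: str, description: str = "tmenet") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *map(str, genes)]) + "\n")


def read_gmt(path: str) -> Dict[str, List[str]]:
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_edgelist(net: nx.DiGraph, path: str) -> None:
    rows = [
        {"source": u, "target": v, "weight": d.get("weight", 1.0)}
        for u, v, d in net.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["source", "target", "weight"])
    with open(path, "w") as fh:
        fh.write("# nodes: " + ",".join(map(str, net.nodes)) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_edgelist(path: str) -> nx.DiGraph:
    with open(path) as fh:
        first = fh.readline()
        nodes: list = []
        if first.startswith("# nodes:"):
            raw = first.split(":", 1)[1].strip()
            nodes = [n for n in raw.split(",") if n]
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    net = nx.DiGraph()
    net.add_nodes_from(nodes)
    for row in df.itertuples(index=False):
        net.add_edge(str(row.source), str(row.target), weight=float(row.weight))
    return net


def write_scores(scores: pd.DataFrame, path: str) -> None:
    scores.to_csv(path, sep="\t")


def read_scores(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)
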