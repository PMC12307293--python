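"""Ligand-receptor communication strengths and the cell-type network.

The strength of a pair from sender s to receiver r is a saturating
mass-action (Hill) score

    strength = L*R / (hill_k + L*R),  in [0, 1),

where L is the trimmed mean log-normalized ligand expression in s
(geometric mean across subunits for multi-subunit ligands) and R the
same for the receptor in r. Cell types with fewer than ``min_cells``
cells contribute no interactions. This is a documented simplified
surrogate for full communication-probability machinery: everything
downstream (pruning, hierarchy, motifs) needs only a nonnegative
directed strength matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import trim_mean

from ._utils import ConfigError, lognorm, logger

LABEL_KEY = "cell_type"


@dataclass
class LRPair:
    """A ligand-receptor pair; multi-subunit genes are lists."""

    ligand: List[str]
    receptor: List[str]
    pathway: str = ""

    def __post_init__(self):
        if isinstance(self.ligand, str):
            self.ligand = self.ligand.split("+")
        if isinstance(self.receptor, str):
            self.receptor = self.receptor.split("+")
        if not self.ligand or not self.receptor:
            raise ConfigError("pair needs at least one ligand and one receptor gene")

    @property
    def name(self) -> str:
        return "+".join(self.ligand) + "->" + "+".join(self.receptor)


@dataclass
class CommConfig:
    min_cells: int = 5
    hill_k: float = 0.5
    trim_frac: float = 0.1

    def __post_init__(self):
        if self.min_cells < 1:
            raise ConfigError("min_cells must be >= 1")
        if self.hill_k <= 0:
            raise ConfigError("hill_k must be positive")
        if not 0 <= self.trim_frac < 0.5:
            raise ConfigError("trim_frac must be in [0, 0.5)")


def read_lr_pairs(path: str) -> List[LRPair]:
    """Read a TSV with columns ligand, receptor[, pathway]; '+' joins subunits."""
    df = pd.read_csv(path, sep="\t")
    return [
        LRPair(
            ligand=str(row["ligand"]),
            receptor=str(row["receptor"]),
            pathway=str(row.get("pathway", "")),
        )
        for _, row in df.iterrows()
    ]


def _type_means(adata: ad.AnnData, config: CommConfig, label_key: str):
    """Trimmed mean log-normalized expression per (cell type, gene)."""
    labels = np.asarray(adata.obs[label_key].astype(str))
    logX = lognorm(adata.X)
    gene_idx = {g: i for i, g in enumerate(adata.var_names)}
    all_types = sorted(set(labels))
    means: Dict[str, np.ndarray] = {}
    excluded = []
    for t in all_types:
        mask = labels == t
        if mask.sum() < config.min_cells:
            excluded.append(t)
            continue
        means[t] = trim_mean(logX[mask], config.trim_frac, axis=0)
    return all_types, means, excluded, gene_idx


def _set_level(mean_vec, genes: Sequence[str], gene_idx) -> Optional[float]:
    """Geometric mean across subunits; None when a gene is absent."""
    vals = []
    for g in genes:
        if g not in gene_idx:
            return None
        vals.append(mean_vec[gene_idx[g]])
    vals = np.asarray(vals, dtype=float)
    if np.any(vals <= 0):
        return 0.0
    return float(np.exp(np.mean(np.log(vals))))


def comm_strength(
    adata: ad.AnnData,
    pairs: Sequence[LRPair],
    config: Optional[CommConfig] = None,
    label_key: str = LABEL_KEY,
) -> pd.DataFrame:
    """Per-(pair, sender, receiver) Hill strengths.

    Missing pair genes yield strength 0 with a logged note. The full
    cell-type list (including below-min_cells types) is attached in
    ``df.attrs["cell_types"]`` so aggregation can keep isolated nodes.
    """
    config = config or CommConfig()
    if label_key not in adata.obs:
        raise ValueError(f"missing label column {label_key!r}")
    all_types, means, excluded, gene_idx = _type_means(adata, config, label_key)
    if excluded:
        logger.info(
            "cell types below min_cells=%d excluded: %s", config.min_cells, excluded
        )
    rows = []
    for pair in pairs:
        ligand_known = all(g in gene_idx for g in pair.ligand)
        receptor_known = all(g in gene_idx for g in pair.receptor)
        if not (ligand_known and receptor_known):
            logger.info("pair %s has absent gene(s); strength 0", pair.name)
        for s in means:
            L = _set_level(means[s], pair.ligand, gene_idx) if ligand_known else 0.0
            for r in means:
                R = (
                    _set_level(means[r], pair.receptor, gene_idx)
                    if receptor_known
                    else 0.0
                )
                lr = L * R
                rows.append(
                    {
                        "pair": pair.name,
                        "pathway": pair.pathway,
                        "sender": s,
                        "receiver": r,
                        "strength": lr / (config.hill_k + lr),
                    }
                )
    df = pd.DataFrame(
        rows, columns=["pair", "pathway", "sender", "receiver", "strength"]
    )
    df.attrs["cell_types"] = all_types
    return df


def aggregate_network(strengths: pd.DataFrame) -> nx.DiGraph:
    """Sum pair strengths into a weighted directed cell-type network.

    Every cell type becomes a node (isolated if it carries no
    interactions); per-edge pathway breakdown is kept as an attribute.
    """
    if strengths.empty and not strengths.attrs.get("cell_types"):
        raise ValueError("empty strength table")
    net = nx.DiGraph()
    nodes = strengths.attrs.get("cell_types")
    if nodes is None:
        nodes = sorted(set(strengths["sender"]) | set(strengths["receiver"]))
    net.add_nodes_from(nodes)
    grouped = strengths.groupby(["sender", "receiver"])["strength"].sum()
    for (s, r), w in grouped.items():
        if w > 0:
            breakdown = (
                strengths[
                    (strengths["sender"] == s) & (strengths["receiver"] == r)
                ]
                .groupby("pathway")["strength"]
                .sum()
                .to_dict()
            )
            net.add_edge(s, r, weight=float(w), pathways=breakdown)
    return net


def compare_groups(
    expr_groups: Dict[str, Sequence[ad.AnnData]],
    pairs: Sequence[LRPair],
    config: Optional[CommConfig] = None,
    n_perm: int = 999,
    seed: int = 0,
    label_key: str = LABEL_KEY,
) -> pd.DataFrame:
    """Permutation test of per-(pair, sender, receiver) strength differences.

    Samples (patients) are the replicates; the difference is
    mean(group2) - mean(group1) in the dict's insertion order, and the
    two-sided p uses add-one smoothing:
    p = (1 + #{|diff_perm| >= |diff_obs|}) / (1 + n_perm).
    """
    config = config or CommConfig()
    if len(expr_groups) != 2:
        raise ValueError("exactly two groups are required")
    (g1, samples1), (g2, samples2) = expr_groups.items()
    if len(samples1) < 2 or len(samples2) < 2:
        raise ValueError("each group needs at least 2 samples")
    per_sample = []
    for adata in list(samples1) + list(samples2):
        tab = comm_strength(adata, pairs, config, label_key=label_key)
        per_sample.append(tab.set_index(["pair", "sender", "receiver"])["strength"])
    mat = pd.concat(per_sample, axis=1).fillna(0.0)
    mat.columns = range(mat.shape[1])
    n1 = len(samples1)
    labels = np.array([0] * n1 + [1] * len(samples2))
    values = mat.to_numpy()

    def diff(lab):
        return values[:, lab == 1].mean(axis=1) - values[:, lab == 0].mean(axis=1)

    obs = diff(labels)
    rng = np.random.default_rng(seed)
    count_ge = np.zeros(len(obs), dtype=int)
    for _ in range(n_perm):
        count_ge += np.abs(diff(rng.permutation(labels))) >= np.abs(obs)
    p = (1 + count_ge) / (1 + n_perm)
    out = mat.index.to_frame(index=False)
    out[f"mean_{g1}"] = values[:, :n1].mean(axis=1)
    out[f"mean_{g2}"] = values[:, n1:].mean(axis=1)
    out["diff"] = obs
    out["p_perm"] = p
    return out
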