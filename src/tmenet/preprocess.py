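"""Quality-control filters and per-cell-type marker signatures.

Boundary semantics are deliberately literal: cells with library size
<= min_umi_exclusive OR mitochondrial fraction >= max_mito_frac_exclusive
are excluded; genes detected in fewer than min_cells_per_gene cells are
dropped (exactly-at-threshold survives). Spot matrices are filtered
spots-first, then genes by total count and spot prevalence.

Markers are ranked per cell type by a one-vs-rest two-sided Wilcoxon
rank-sum test on log-normalized expression with Benjamini-Hochberg
adjustment; genes passing adjusted p and average natural-log fold-change
thresholds are ordered by fold change and truncated to the top n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from ._utils import ConfigError, as_dense, lognorm, logger

LABEL_KEY = "cell_type"


@dataclass
class QCThresholds:
    min_umi_exclusive: int = 2000
    max_mito_frac_exclusive: float = 0.05
    min_cells_per_gene: int = 3
    min_genes_per_spot: int = 200
    min_counts_per_gene_spatial: int = 10
    min_spots_per_gene: int = 3
    mito_prefix: str = "MT-"

    def __post_init__(self):
        for name in (
            "min_umi_exclusive",
            "min_cells_per_gene",
            "min_genes_per_spot",
            "min_counts_per_gene_spatial",
            "min_spots_per_gene",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.max_mito_frac_exclusive <= 1:
            raise ConfigError("max_mito_frac_exclusive must be in [0, 1]")


@dataclass
class MarkerCriteria:
    max_adj_p: float = 0.05
    min_avg_logfc: float = 0.15
    top_n: int = 30

    def __post_init__(self):
        if not 0 < self.max_adj_p <= 1:
            raise ConfigError("max_adj_p must be in (0, 1]")
        if self.top_n < 1:
            raise ConfigError("top_n must be >= 1")


@dataclass
class SignatureSet:
    """Named, ordered gene lists with the criteria that produced them."""

    sets: Dict[str, List[str]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ConfigError(f"signature {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ConfigError(f"signature {name!r} has duplicate genes")

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


def _mito_mask(adata: ad.AnnData, prefix: str) -> np.ndarray:
    return np.array([str(g).startswith(prefix) for g in adata.var_names])


def filter_cells(adata: ad.AnnData, qc: Optional[QCThresholds] = None) -> ad.AnnData:
    """Drop low-depth and high-mitochondrial cells.

    Retains cells with library size strictly greater than
    ``min_umi_exclusive`` AND mito fraction strictly below
    ``max_mito_frac_exclusive``. Removal counts per criterion are stored
    in ``uns["qc_report"]["cells"]``.
    """
    qc = qc or QCThresholds()
    X = as_dense(adata.X)
    libsize = X.sum(axis=1)
    low_depth = libsize <= qc.min_umi_exclusive

    mito = _mito_mask(adata, qc.mito_prefix)
    if mito.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(libsize > 0, X[:, mito].sum(axis=1) / libsize, 0.0)
        high_mito = frac >= qc.max_mito_frac_exclusive
    else:
        high_mito = np.zeros(adata.n_obs, dtype=bool)
        if qc.max_mito_frac_exclusive < 1:
            warnings.warn(
                f"no genes match mito prefix {qc.mito_prefix!r}; "
                "mitochondrial criterion skipped"
            )
            logger.warning("mito criterion skipped: no %r genes", qc.mito_prefix)

    keep = ~(low_depth | high_mito)
    out = adata[keep].copy()
    out.uns["qc_report"] = dict(adata.uns.get("qc_report", {}))
    out.uns["qc_report"]["cells"] = {
        "input": int(adata.n_obs),
        "removed_low_umi": int(low_depth.sum()),
        "removed_high_mito": int(high_mito.sum()),
        "retained": int(keep.sum()),
    }
    return out


def filter_genes(
    adata: ad.AnnData, qc: Optional[QCThresholds] = None, flag_only: bool = False
) -> ad.AnnData:
    """Remove genes with nonzero counts in fewer than ``min_cells_per_gene`` cells.

    With ``flag_only`` the genes are kept but marked undetected in
    ``var["detected"]`` instead of being removed.
    """
    qc = qc or QCThresholds()
    X = adata.X
    if sp.issparse(X):
        n_cells = np.asarray((X > 0).sum(axis=0)).ravel()
    else:
        n_cells = (np.asarray(X) > 0).sum(axis=0)
    detected = n_cells >= qc.min_cells_per_gene
    if flag_only:
        out = adata.copy()
        out.var["detected"] = detected
        return out
    if not detected.any():
        raise ValueError("no genes survive the detection filter")
    out = adata[:, detected].copy()
    out.uns["qc_report"] = dict(adata.uns.get("qc_report", {}))
    out.uns["qc_report"]["genes"] = {
        "input": int(adata.n_vars),
        "removed": int((~detected).sum()),
        "retained": int(detected.sum()),
    }
    return out


def filter_spots(adata: ad.AnnData, qc: Optional[QCThresholds] = None) -> ad.AnnData:
    """Spatial QC: spots first (detected genes), then genes (counts, prevalence)."""
    qc = qc or QCThresholds()
    X = as_dense(adata.X)
    detected_genes = (X > 0).sum(axis=1)
    keep_spots = detected_genes >= qc.min_genes_per_spot
    Xs = X[keep_spots]
    totals = Xs.sum(axis=0)
    prevalence = (Xs > 0).sum(axis=0)
    keep_genes = (totals >= qc.min_counts_per_gene_spatial) & (
        prevalence >= qc.min_spots_per_gene
    )
    if not keep_spots.any() or not keep_genes.any():
        raise ValueError("no spots or genes survive the spatial filter")
    out = adata[keep_spots][:, keep_genes].copy()
    out.uns["qc_report"] = dict(adata.uns.get("qc_report", {}))
    out.uns["qc_report"]["spots"] = {
        "input_spots": int(adata.n_obs),
        "retained_spots": int(keep_spots.sum()),
        "input_genes": int(adata.n_vars),
        "retained_genes": int(keep_genes.sum()),
    }
    return out


def rank_markers(
    adata: ad.AnnData,
    criteria: Optional[MarkerCriteria] = None,
    label_key: str = LABEL_KEY,
) -> SignatureSet:
    """Top-n marker signatures per cell type (one-vs-rest rank-sum).

    Fold change is the Seurat-style difference of log(mean(expm1) + 1)
    between the type and the rest, on log-normalized expression. Genes
    must pass both the BH-adjusted p and fold-change thresholds with
    positive fold change; ordering is fold change descending, ties by
    adjusted p then gene name.
    """
    criteria = criteria or MarkerCriteria()
    if label_key not in adata.obs:
        raise ValueError(f"missing label column {label_key!r}")
    labels = np.asarray(adata.obs[label_key].astype(str))
    types = sorted(set(labels))
    if len(types) < 2:
        raise ValueError("need at least two cell types to rank markers")

    logX = lognorm(adata.X)
    genes = np.asarray(adata.var_names)
    sets: Dict[str, List[str]] = {}
    for t in types:
        in_t = labels == t
        if in_t.sum() < 3:
            warnings.warn(f"cell type {t!r} has fewer than 3 cells; skipped")
            continue
        x_in, x_out = logX[in_t], logX[~in_t]
        with np.errstate(invalid="ignore"):
            _, p = mannwhitneyu(
                x_in, x_out, alternative="two-sided", axis=0, method="asymptotic"
            )
        p = np.where(np.isnan(p), 1.0, p)
        adj_p = multipletests(p, method="fdr_bh")[1]
        lfc = np.log(np.expm1(x_in).mean(axis=0) + 1) - np.log(
            np.expm1(x_out).mean(axis=0) + 1
        )
        passing = (adj_p <= criteria.max_adj_p) & (lfc >= criteria.min_avg_logfc) & (
            lfc > 0
        )
        order = pd.DataFrame(
            {"gene": genes[passing], "lfc": lfc[passing], "adj_p": adj_p[passing]}
        ).sort_values(
            by=["lfc", "adj_p", "gene"], ascending=[False, True, True], kind="mergesort"
        )
        top = order["gene"].head(criteria.top_n).tolist()
        if top:
            sets[t] = top
    return SignatureSet(
        sets=sets,
        provenance={
            "max_adj_p": criteria.max_adj_p,
            "min_avg_logfc": criteria.min_avg_logfc,
            "top_n": criteria.top_n,
            "test": "wilcoxon rank-sum, one-vs-rest, two-sided, BH-adjusted",
        },
    )
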