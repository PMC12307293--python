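"""Gene-signature scoring: control-bin module score, AUC recovery score,
and single-sample GSEA.

* ``module_score`` — mean signature expression minus the mean of
  expression-matched control genes (drawn per signature gene from its
  average-expression bin); sensitive to the expression scale.
* ``auc_set_score`` — area under the recovery curve of signature genes
  within the top fraction of each cell's expression ranking; rank-based,
  invariant to per-cell monotone transforms.
* ``ssgsea`` — per-sample weighted running-sum enrichment (rank weight
  exponent alpha, default 0.25), optionally normalized per signature by
  its score range across samples; rank-based.

All three return a samples-by-signatures ``pandas.DataFrame``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Union

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import ConfigError, as_dense, lognorm

SignatureLike = Union[Dict[str, List[str]], "SignatureSet"]


@dataclass
class SsgseaConfig:
    alpha: float = 0.25
    normalize: bool = True

    def __post_init__(self):
        if self.alpha < 0:
            raise ConfigError("alpha must be >= 0")


def _as_sets(sigs: SignatureLike) -> Dict[str, List[str]]:
    if hasattr(sigs, "sets"):
        return dict(sigs.sets)
    return dict(sigs)


def _matrix(data, normalize: str = "none"):
    """(values, obs_names, var_names) from AnnData or DataFrame."""
    if isinstance(data, ad.AnnData):
        X = as_dense(data.X)
        obs, var = list(map(str, data.obs_names)), list(map(str, data.var_names))
    elif isinstance(data, pd.DataFrame):
        X = data.to_numpy(dtype=float)
        obs, var = list(map(str, data.index)), list(map(str, data.columns))
    else:
        raise TypeError("expected AnnData or DataFrame")
    if normalize == "lognorm":
        X = lognorm(X)
    return X, obs, var


def _present_genes(name: str, genes: List[str], var_index: Dict[str, int]):
    present = [g for g in genes if g in var_index]
    missing = [g for g in genes if g not in var_index]
    if missing and present:
        warnings.warn(
            f"signature {name!r}: {len(missing)} gene(s) absent from the matrix; dropped"
        )
    if not present:
        raise ValueError(f"signature {name!r} has no genes in the matrix")
    return present


def module_score(
    data,
    sigs: SignatureLike,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    normalize: str = "lognorm",
) -> pd.DataFrame:
    """Control-bin module score per cell and signature.

    Genes are binned into ``n_bins`` by dataset-wide average expression;
    each signature gene contributes up to ``n_ctrl`` control genes drawn
    (without replacement, seeded) from its own bin. The score is the mean
    signature expression minus the mean control expression.
    """
    X, obs, var = _matrix(data, normalize)
    var_index = {g: i for i, g in enumerate(var)}
    avg = X.mean(axis=0)
    n_bins_eff = min(n_bins, len(var))
    bins = pd.qcut(rankdata(avg, method="ordinal"), n_bins_eff, labels=False)
    bin_members = {b: np.nonzero(bins == b)[0] for b in range(n_bins_eff)}

    rng = np.random.default_rng(seed)
    out = {}
    for name, genes in _as_sets(sigs).items():
        present = _present_genes(name, genes, var_index)
        sig_idx = np.array([var_index[g] for g in present])
        ctrl_idx: List[np.ndarray] = []
        for gi in sig_idx:
            members = bin_members[int(bins[gi])]
            take = min(n_ctrl, len(members))
            ctrl_idx.append(rng.choice(members, size=take, replace=False))
        ctrl = np.concatenate(ctrl_idx)
        out[name] = X[:, sig_idx].mean(axis=1) - X[:, ctrl].mean(axis=1)
    df = pd.DataFrame(out, index=obs)
    df.attrs["method"] = "module_score"
    return df


def auc_set_score(
    data,
    sigs: SignatureLike,
    top_frac: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """AUC of the signature-gene recovery curve within the top-ranked genes.

    Per cell, genes are ranked by decreasing expression (ties broken by a
    seeded gene shuffle); with R = ceil(top_frac * n_genes) and h(x) the
    number of signature genes among the top x, the score is
    sum_x h(x) / max possible, in [0, 1].
    """
    if not 0 < top_frac <= 1:
        raise ConfigError("top_frac must be in (0, 1]")
    X, obs, var = _matrix(data)
    n_genes = len(var)
    R = int(np.ceil(top_frac * n_genes))
    rng = np.random.default_rng(seed)
    shuffle = rng.permutation(n_genes)
    Xs = X[:, shuffle]
    var_s = [var[i] for i in shuffle]
    var_index = {g: i for i, g in enumerate(var_s)}
    # stable argsort on the shuffled axis = random tie-break, deterministic
    order = np.argsort(-Xs, axis=1, kind="stable")
    position = np.empty_like(order)
    rows = np.arange(X.shape[0])[:, None]
    position[rows, order] = np.arange(n_genes)[None, :]

    out = {}
    for name, genes in _as_sets(sigs).items():
        present = _present_genes(name, genes, var_index)
        sig_idx = np.array([var_index[g] for g in present])
        pos = position[:, sig_idx]  # cells x signature genes
        contrib = np.where(pos < R, R - pos, 0)
        auc = contrib.sum(axis=1).astype(float)
        m = min(len(sig_idx), R)
        max_auc = m * (m + 1) / 2 + (R - m) * m
        out[name] = auc / max_auc
    df = pd.DataFrame(out, index=obs)
    df.attrs["method"] = "auc_set_score"
    return df


def _ssgsea_sample(ranks: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Weighted running-sum enrichment for one sample.

    ``ranks`` are ascending average ranks (top gene = n); the walk goes
    from the highest-ranked gene down.
    """
    order = np.argsort(-ranks, kind="stable")
    in_ordered = in_set[order]
    w = np.abs(ranks[order]) ** alpha
    w_in = np.where(in_ordered, w, 0.0)
    denom_in = w_in.sum()
    n_out = (~in_set).sum()
    ecdf_in = np.cumsum(w_in) / denom_in
    ecdf_out = np.cumsum(~in_ordered) / n_out
    return float(np.sum(ecdf_in - ecdf_out))


def ssgsea(
    data,
    sigs: SignatureLike,
    config: Optional[SsgseaConfig] = None,
) -> pd.DataFrame:
    """Single-sample GSEA scores for bulk sample-by-gene expression.

    Signatures with fewer than 2 genes in the matrix are skipped with a
    warning. With ``normalize`` each signature's scores are divided by
    their (max - min) across samples.
    """
    config = config or SsgseaConfig()
    X, obs, var = _matrix(data)
    var_index = {g: i for i, g in enumerate(var)}
    ranks = rankdata(X, axis=1, method="average")

    out = {}
    for name, genes in _as_sets(sigs).items():
        present = [g for g in genes if g in var_index]
        if len(present) < 2:
            warnings.warn(f"signature {name!r} has < 2 genes in the matrix; skipped")
            continue
        in_set = np.zeros(len(var), dtype=bool)
        in_set[[var_index[g] for g in present]] = True
        scores = np.array(
            [_ssgsea_sample(ranks[i], in_set, config.alpha) for i in range(X.shape[0])]
        )
        if config.normalize:
            rng_ = scores.max() - scores.min()
            if rng_ > 0:
                scores = scores / rng_
            else:
                warnings.warn(
                    f"signature {name!r}: zero score range; normalization skipped"
                )
        out[name] = scores
    df = pd.DataFrame(out, index=obs)
    df.attrs["method"] = "ssgsea"
    df.attrs["alpha"] = config.alpha
    df.attrs["normalized"] = config.normalize
    return df


class SsgseaScorer(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`ssgsea` for pipeline composition.

    ``fit`` records the gene universe; ``transform`` maps a sample-by-gene
    frame to a sample-by-signature score frame.
    """

    def __init__(self, signatures: Optional[Dict[str, List[str]]] = None,
                 alpha: float = 0.25, normalize: bool = True):
        self.signatures = signatures
        self.alpha = alpha
        self.normalize = normalize

    def fit(self, X, y=None):
        if not self.signatures:
            raise ValueError("signatures must be provided")
        _, _, var = _matrix(X)
        self.genes_ = list(var)
        self.signature_names_ = list(self.signatures)
        return self

    def transform(self, X):
        if not hasattr(self, "genes_"):
            raise ValueError("SsgseaScorer is not fitted")
        return ssgsea(
            X, self.signatures, SsgseaConfig(alpha=self.alpha, normalize=self.normalize)
        )
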