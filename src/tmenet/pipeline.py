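"""End-to-end orchestration: synthetic data or user inputs through QC,
markers, communication network, hierarchy, motif census + null, bulk
scoring and TME classification, with a JSON run manifest.

Every stage derives its own seed from the global seed and the stage name,
so runs are reproducible end to end and stages never share random
streams. The manifest records per-stage status, output files with sha256
checksums, and headline counts, making reruns auditable by hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import io as tio
from ._utils import derive_seed, logger
from .classify import ClusterConfig, cluster_scores, label_subtypes
from .communication import CommConfig, LRPair, aggregate_network, comm_strength
from .hierarchy import find_root, layer_nodes, prune_edges
from .motifs import enumerate_motifs
from .nullmodel import NullConfig, motif_significance
from .preprocess import MarkerCriteria, QCThresholds, filter_cells, filter_genes, rank_markers
from .scoring import SsgseaConfig, ssgsea
from .synthetic import (
    SyntheticBulkConfig,
    SyntheticGraphSpec,
    SyntheticScConfig,
    gen_bulk_mixtures,
    gen_sc_expression,
    gen_weighted_digraph,
)

DEFAULT_STAGES = (
    "synthetic_sc",
    "qc",
    "markers",
    "commnet",
    "hierarchy",
    "motifs",
    "synthetic_bulk",
    "ssgsea",
    "tme",
)


@dataclass
class RunConfig:
    outdir: str = "tmenet_run"
    seed: int = 0
    stages: Dict[str, bool] = field(default_factory=dict)
    sc: SyntheticScConfig = field(default_factory=SyntheticScConfig)
    bulk: Optional[SyntheticBulkConfig] = None
    # demo-scale QC: synthetic cells carry ~100 counts over a few hundred
    # genes, so the depth threshold is scaled down from the real-data default
    qc: QCThresholds = field(
        default_factory=lambda: QCThresholds(
            min_umi_exclusive=30, max_mito_frac_exclusive=0.25
        )
    )
    markers: MarkerCriteria = field(default_factory=MarkerCriteria)
    comm: CommConfig = field(default_factory=lambda: CommConfig(min_cells=5))
    null_model: NullConfig = field(default_factory=lambda: NullConfig(n_random=200))
    ssgsea: SsgseaConfig = field(default_factory=SsgseaConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    min_edge_weight: float = 1e-4
    motif_sizes: List[int] = field(default_factory=lambda: [2, 3])
    log_level: str = "INFO"

    def enabled(self, stage: str) -> bool:
        return self.stages.get(stage, True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        simple = {"outdir", "seed", "stages", "min_edge_weight", "motif_sizes", "log_level"}
        nested = {
            "sc": SyntheticScConfig,
            "bulk": SyntheticBulkConfig,
            "qc": QCThresholds,
            "markers": MarkerCriteria,
            "comm": CommConfig,
            "null_model": NullConfig,
            "ssgsea": SsgseaConfig,
            "cluster": ClusterConfig,
        }
        for key, value in raw.items():
            if key in simple:
                kwargs[key] = value
            elif key in nested:
                if key == "sc" and "lr_plants" in value:
                    value["lr_plants"] = [tuple(p) for p in value["lr_plants"]]
                kwargs[key] = nested[key](**value)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**kwargs)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}

    def record(stage: str, status: str, **info):
        manifest["stages"][stage] = {"status": status, **info}
        logger.info("stage %s: %s", stage, status)

    def save(path: str):
        manifest["outputs"][os.path.relpath(path, config.outdir)] = _sha256(path)

    adata = markers = net = None
    # --- single-cell side -------------------------------------------------
    if config.enabled("synthetic_sc"):
        sc_cfg = config.sc
        sc_cfg.seed = derive_seed(config.seed, "synthetic_sc")
        adata = gen_sc_expression(sc_cfg)
        d = os.path.join(config.outdir, "sc")
        tio.write_expression(adata, d)
        for f in ("matrix.mtx", "genes.tsv", "barcodes.tsv", "labels.tsv"):
            save(os.path.join(d, f))
        record("synthetic_sc", "ok", cells=adata.n_obs, genes=adata.n_vars)
    else:
        record("synthetic_sc", "skipped")

    if config.enabled("qc"):
        if adata is None:
            raise RuntimeError("stage 'qc' requires output of stage 'synthetic_sc'")
        adata = filter_genes(filter_cells(adata, config.qc), config.qc)
        with open(os.path.join(config.outdir, "qc_report.json"), "w") as fh:
            json.dump(adata.uns["qc_report"], fh, indent=2)
        save(os.path.join(config.outdir, "qc_report.json"))
        record("qc", "ok", **adata.uns["qc_report"].get("cells", {}))
    else:
        record("qc", "skipped")

    if config.enabled("markers"):
        if adata is None:
            raise RuntimeError("stage 'markers' requires single-cell data")
        markers = rank_markers(adata, config.markers)
        path = os.path.join(config.outdir, "markers.gmt")
        tio.write_gmt(markers.sets, path)
        save(path)
        record("markers", "ok", n_signatures=len(markers.sets))
    else:
        record("markers", "skipped")

    if config.enabled("commnet"):
        if adata is None:
            raise RuntimeError("stage 'commnet' requires single-cell data")
        plants = adata.uns.get("synthetic", {}).get("lr_plants", [])
        pairs = [
            LRPair(ligand=[lig], receptor=[rec], pathway=f"planted_{i}")
            for i, (lig, rec, _, _, _) in enumerate(plants)
        ]
        if not pairs:
            raise RuntimeError("stage 'commnet' has no ligand-receptor pairs")
        strengths = comm_strength(adata, pairs, config.comm)
        strengths.to_csv(os.path.join(config.outdir, "strengths.tsv"), sep="\t", index=False)
        save(os.path.join(config.outdir, "strengths.tsv"))
        net = aggregate_network(strengths)
        tio.write_edgelist(net, os.path.join(config.outdir, "network.tsv"))
        save(os.path.join(config.outdir, "network.tsv"))
        record("commnet", "ok", nodes=net.number_of_nodes(), edges=net.number_of_edges())
    else:
        record("commnet", "skipped")

    if config.enabled("hierarchy"):
        if net is None:
            raise RuntimeError("stage 'hierarchy' requires output of stage 'commnet'")
        pruned = prune_edges(net, config.min_edge_weight)
        root = find_root(pruned)
        layout = layer_nodes(pruned, root)
        path = os.path.join(config.outdir, "hierarchy.json")
        with open(path, "w") as fh:
            json.dump(layout.to_dict(), fh, indent=2)
        save(path)
        record("hierarchy", "ok", root=root, n_layers=1 + max(layout.layers.values()))
        net = pruned
    else:
        record("hierarchy", "skipped")

    if config.enabled("motifs"):
        if net is None:
            raise RuntimeError("stage 'motifs' requires a network")
        census = enumerate_motifs(net, sizes=config.motif_sizes)
        census.table.to_csv(os.path.join(config.outdir, "census.tsv"), sep="\t")
        save(os.path.join(config.outdir, "census.tsv"))
        null_cfg = config.null_model
        null_cfg.seed = derive_seed(config.seed, "motif_null")
        stats = motif_significance(net, null_cfg, sizes=config.motif_sizes)
        stats.table.to_csv(os.path.join(config.outdir, "motif_null.tsv"), sep="\t")
        save(os.path.join(config.outdir, "motif_null.tsv"))
        record(
            "motifs",
            "ok",
            n_classes=int((census.table["count"] > 0).sum()),
            n_random=null_cfg.n_random,
        )
    else:
        record("motifs", "skipped")

    # --- bulk side --------------------------------------------------------
    bulk = None
    if config.enabled("synthetic_bulk"):
        bulk_cfg = config.bulk or SyntheticBulkConfig(
            signatures={f"sig{j}": list(range(20 * j, 20 * j + 15)) for j in range(4)}
        )
        bulk_cfg.seed = derive_seed(config.seed, "synthetic_bulk")
        bulk = gen_bulk_mixtures(bulk_cfg)
        d = os.path.join(config.outdir, "bulk")
        tio.write_expression(bulk, d)
        save(os.path.join(d, "matrix.mtx"))
        record("synthetic_bulk", "ok", samples=bulk.n_obs, genes=bulk.n_vars)
    else:
        record("synthetic_bulk", "skipped")

    scores = None
    if config.enabled("ssgsea"):
        if bulk is None:
            raise RuntimeError("stage 'ssgsea' requires output of stage 'synthetic_bulk'")
        scores = ssgsea(bulk, bulk.uns["signatures"], config.ssgsea)
        tio.write_scores(scores, os.path.join(config.outdir, "scores.tsv"))
        save(os.path.join(config.outdir, "scores.tsv"))
        record("ssgsea", "ok", samples=scores.shape[0], signatures=scores.shape[1])
    else:
        record("ssgsea", "skipped")

    if config.enabled("tme"):
        if scores is None:
            raise RuntimeError("stage 'tme' requires output of stage 'ssgsea'")
        cl_cfg = config.cluster
        cl_cfg.seed = derive_seed(config.seed, "tme")
        assign = cluster_scores(scores, cl_cfg)
        sig_names = list(scores.columns)
        half = max(1, len(sig_names) // 2)
        assign = label_subtypes(assign, sig_names[:half], sig_names[half:])
        out = assign.assignments.to_frame()
        out["label"] = assign.sample_labels
        out.to_csv(os.path.join(config.outdir, "tme_assignment.tsv"), sep="\t")
        save(os.path.join(config.outdir, "tme_assignment.tsv"))
        assign.centroids.to_csv(os.path.join(config.outdir, "tme_centroids.tsv"), sep="\t")
        save(os.path.join(config.outdir, "tme_centroids.tsv"))
        record("tme", "ok", chosen_k=assign.chosen_k)
    else:
        record("tme", "skipped")

    manifest["params_hash"] = hashlib.sha256(
        json.dumps(_config_dict(config), sort_keys=True, default=str).encode()
    ).hexdigest()
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    out = {}
    for key, value in vars(config).items():
        try:
            out[key] = asdict(value) if hasattr(value, "__dataclass_fields__") else value
        except TypeError:
            out[key] = str(value)
    return out
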