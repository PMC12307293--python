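"""Unsupervised TME subtyping from signature-score matrices.

Samples are clustered on z-scaled signature scores with either k-means
or Ward-linkage hierarchical clustering, sweeping k over a range
(default 2..10) and selecting k by mean silhouette (gap statistic and
fixed-k modes available). Clusters are then given semantic labels from
their centroids: a median split of the barrier index and the exhaustion
index across clusters maps each cluster to barrier-dominant,
barrier-with-exhaustion, exhaustion-dominant, or desert.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import silhouette_score

from ._utils import ConfigError

WEAK_SILHOUETTE = 0.25

SEMANTIC_LABELS = (
    "barrier_dominant",
    "barrier_with_exhaustion",
    "exhaustion_dominant",
    "desert",
)


@dataclass
class ClusterConfig:
    method: str = "ward"  # ward | kmeans
    k_min: int = 2
    k_max: int = 10
    selection: str = "silhouette"  # silhouette | gap | fixed_k
    fixed_k: Optional[int] = None
    n_init: int = 25
    seed: int = 0
    scaling: str = "zscore"  # zscore | none

    def __post_init__(self):
        if not 2 <= self.k_min <= self.k_max:
            raise ConfigError("need 2 <= k_min <= k_max")
        if self.method not in ("ward", "kmeans"):
            raise ConfigError(f"unknown method {self.method!r}")
        if self.selection not in ("silhouette", "gap", "fixed_k"):
            raise ConfigError(f"unknown selection {self.selection!r}")
        if self.selection == "fixed_k" and self.fixed_k is None:
            raise ConfigError("fixed_k selection requires fixed_k")
        if self.scaling not in ("zscore", "none"):
            raise ConfigError(f"unknown scaling {self.scaling!r}")


@dataclass
class TMEAssignment:
    """Cluster assignment with centroids and optional semantic labels."""

    assignments: pd.Series  # sample -> cluster int
    chosen_k: int
    centroids: pd.DataFrame  # cluster x signature (scaled space)
    silhouettes: Dict[int, float] = field(default_factory=dict)
    weak_structure: bool = False
    cluster_labels: Dict[int, str] = field(default_factory=dict)

    @property
    def sample_labels(self) -> pd.Series:
        if not self.cluster_labels:
            raise ValueError("semantic labels not assigned; run label_subtypes")
        return self.assignments.map(self.cluster_labels)


class TMEClassifier(BaseEstimator, ClusterMixin):
    """Model-selecting clustering estimator over signature scores.

    Parameters mirror :class:`ClusterConfig`. After ``fit``:
    ``labels_`` (cluster per sample), ``chosen_k_``, ``centroids_``
    (clusters x signatures, scaled space), ``silhouettes_`` (k -> mean
    silhouette) and ``weak_structure_`` (True when the best mean
    silhouette is below 0.25).
    """

    def __init__(
        self,
        method: str = "ward",
        k_min: int = 2,
        k_max: int = 10,
        selection: str = "silhouette",
        fixed_k: Optional[int] = None,
        n_init: int = 25,
        random_state: int = 0,
        scaling: str = "zscore",
    ):
        self.method = method
        self.k_min = k_min
        self.k_max = k_max
        self.selection = selection
        self.fixed_k = fixed_k
        self.n_init = n_init
        self.random_state = random_state
        self.scaling = scaling

    def _config(self) -> ClusterConfig:
        return ClusterConfig(
            method=self.method,
            k_min=self.k_min,
            k_max=self.k_max,
            selection=self.selection,
            fixed_k=self.fixed_k,
            n_init=self.n_init,
            seed=self.random_state,
            scaling=self.scaling,
        )

    def _validate(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            df = X.astype(float)
        else:
            X = np.asarray(X, dtype=float)
            df = pd.DataFrame(
                X,
                index=[f"s{i}" for i in range(X.shape[0])],
                columns=[f"f{j}" for j in range(X.shape[1])],
            )
        if not np.all(np.isfinite(df.to_numpy())):
            raise ValueError("scores must be finite")
        constant = df.columns[df.std(axis=0, ddof=0) == 0]
        if len(constant):
            warnings.warn(f"dropping constant score column(s): {list(constant)}")
            df = df.drop(columns=list(constant))
        if df.shape[1] == 0:
            raise ValueError("no informative score columns remain")
        return df

    def _cluster_once(self, X: np.ndarray, k: int) -> np.ndarray:
        if self.method == "kmeans":
            km = KMeans(
                n_clusters=k,
                n_init=self.n_init,
                random_state=self.random_state,
                init="k-means++",
            )
            return km.fit_predict(X)
        return AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)

    def _gap(self, X: np.ndarray, labels_by_k: Dict[int, np.ndarray]) -> Dict[int, float]:
        rng = np.random.default_rng(self.random_state)
        lo, hi = X.min(axis=0), X.max(axis=0)
        gaps = {}

        def log_wk(data, labels):
            w = 0.0
            for c in np.unique(labels):
                pts = data[labels == c]
                w += ((pts - pts.mean(axis=0)) ** 2).sum()
            return np.log(w + 1e-12)

        refs = [rng.uniform(lo, hi, size=X.shape) for _ in range(10)]
        for k, labels in labels_by_k.items():
            ref_logs = [log_wk(r, self._cluster_once(r, k)) for r in refs]
            gaps[k] = float(np.mean(ref_logs) - log_wk(X, labels))
        return gaps

    def fit(self, X, y=None):
        config = self._config()
        df = self._validate(X)
        k_max = config.k_max
        if df.shape[0] <= k_max:
            k_max = max(config.k_min, df.shape[0] - 1)
            warnings.warn(f"fewer samples than k_max + 1; lowering k_max to {k_max}")
        Xs = df.to_numpy()
        if config.scaling == "zscore":
            Xs = (Xs - Xs.mean(axis=0)) / Xs.std(axis=0, ddof=0)

        ks = range(config.k_min, k_max + 1)
        labels_by_k = {k: self._cluster_once(Xs, k) for k in ks}
        sils = {k: float(silhouette_score(Xs, labels_by_k[k])) for k in ks}
        if config.selection == "fixed_k":
            chosen = int(config.fixed_k)
            if chosen not in labels_by_k:
                labels_by_k[chosen] = self._cluster_once(Xs, chosen)
                sils[chosen] = float(silhouette_score(Xs, labels_by_k[chosen]))
        elif config.selection == "gap":
            gaps = self._gap(Xs, labels_by_k)
            chosen = max(gaps, key=gaps.get)
            self.gaps_ = gaps
        else:
            chosen = max(sils, key=sils.get)

        labels = labels_by_k[chosen]
        self.feature_names_in_ = np.asarray(df.columns)
        self.sample_names_ = list(df.index)
        self.labels_ = labels
        self.chosen_k_ = chosen
        self.silhouettes_ = sils
        self.weak_structure_ = sils[chosen] < WEAK_SILHOUETTE
        self.centroids_ = pd.DataFrame(
            [Xs[labels == c].mean(axis=0) for c in range(chosen)],
            index=range(chosen),
            columns=df.columns,
        )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def to_assignment(self) -> TMEAssignment:
        if not hasattr(self, "labels_"):
            raise ValueError("TMEClassifier is not fitted")
        return TMEAssignment(
            assignments=pd.Series(self.labels_, index=self.sample_names_, name="cluster"),
            chosen_k=self.chosen_k_,
            centroids=self.centroids_.copy(),
            silhouettes=dict(self.silhouettes_),
            weak_structure=self.weak_structure_,
        )


def cluster_scores(
    scores: pd.DataFrame, config: Optional[ClusterConfig] = None
) -> TMEAssignment:
    """Cluster a samples-by-signatures score matrix; see :class:`TMEClassifier`."""
    config = config or ClusterConfig()
    clf = TMEClassifier(
        method=config.method,
        k_min=config.k_min,
        k_max=config.k_max,
        selection=config.selection,
        fixed_k=config.fixed_k,
        n_init=config.n_init,
        random_state=config.seed,
        scaling=config.scaling,
    )
    clf.fit(scores)
    return clf.to_assignment()


def label_subtypes(
    assign: TMEAssignment,
    barrier_sigs: List[str],
    exhaustion_sigs: List[str],
) -> TMEAssignment:
    """Semantic labels from a median split of barrier/exhaustion indices.

    Per cluster: barrier index = mean centroid over the barrier
    signatures, exhaustion index likewise; a cluster is "high" on an
    axis when its index is strictly above the median across clusters.
    high/high -> barrier_with_exhaustion, high/low -> barrier_dominant,
    low/high -> exhaustion_dominant, low/low -> desert.
    """
    for name in list(barrier_sigs) + list(exhaustion_sigs):
        if name not in assign.centroids.columns:
            raise ValueError(f"signature {name!r} not among score columns")
    barrier = assign.centroids[list(barrier_sigs)].mean(axis=1)
    exhaustion = assign.centroids[list(exhaustion_sigs)].mean(axis=1)
    b_high = barrier > barrier.median()
    e_high = exhaustion > exhaustion.median()
    labels = {}
    for c in assign.centroids.index:
        if b_high[c] and e_high[c]:
            labels[c] = "barrier_with_exhaustion"
        elif b_high[c]:
            labels[c] = "barrier_dominant"
        elif e_high[c]:
            labels[c] = "exhaustion_dominant"
        else:
            labels[c] = "desert"
    return TMEAssignment(
        assignments=assign.assignments.copy(),
        chosen_k=assign.chosen_k,
        centroids=assign.centroids.copy(),
        silhouettes=dict(assign.silhouettes),
        weak_structure=assign.weak_structure,
        cluster_labels=labels,
    )
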