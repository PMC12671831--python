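"""Clustering of low-dimensional embeddings and GT-matched unit selection.

The primary clusterer is HDBSCAN (hierarchical density-based clustering,
delegated to scikit-learn's implementation), which infers the cluster
count and labels sparse points as noise (-1). K-means and Gaussian-mixture
baselines assign every point to a cluster, matching the behavior they are
compared against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import HDBSCAN as _SKHDBSCAN
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .errors import ParameterError
from .evaluate import Metrics, f1_against_gt
from .features import Embedding
from .io import NOISE_LABEL, Labeling


@dataclass
class ClusterConfig:
    min_cluster_size: int = 25
    min_samples: Optional[int] = None  # default: min_cluster_size
    baseline_method: str = "kmeans"  # kmeans | gmm
    k: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_cluster_size < 2:
            raise ParameterError("min_cluster_size must be >= 2")
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if self.baseline_method not in ("kmeans", "gmm"):
            raise ParameterError(f"unknown baseline {self.baseline_method!r}")


class HDBSCANClusterer(ClusterMixin, BaseEstimator):
    """Density-based clustering; labels 0..k-1 plus -1 for noise."""

    def __init__(self, min_cluster_size: int = 25, min_samples: Optional[int] = None):
        self.min_cluster_size = min_cluster_size
        self.min_samples = min_samples

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] < self.min_cluster_size:
            warnings.warn(
                f"{X.shape[0]} points < min_cluster_size={self.min_cluster_size}; "
                "labeling everything as noise"
            )
            self.labels_ = np.full(X.shape[0], NOISE_LABEL, dtype=np.int64)
            return self
        ms = self.min_samples if self.min_samples is not None else self.min_cluster_size
        est = _SKHDBSCAN(min_cluster_size=self.min_cluster_size, min_samples=ms)
        labels = est.fit_predict(X).astype(np.int64)
        if labels.max(initial=NOISE_LABEL) == NOISE_LABEL:
            # a lone dense blob: excess-of-mass selection excludes the root
            # cluster, so everything lands in noise; retry allowing one
            est = _SKHDBSCAN(
                min_cluster_size=self.min_cluster_size,
                min_samples=ms,
                allow_single_cluster=True,
            )
            labels = est.fit_predict(X).astype(np.int64)
        self.labels_ = labels
        return self


class BaselineClusterer(ClusterMixin, BaseEstimator):
    """K-means or Gaussian-mixture baseline; every point gets a cluster."""

    def __init__(self, method: str = "kmeans", k: int = 2, random_state: int = 0):
        self.method = method
        self.k = k
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if self.k > X.shape[0]:
            raise ParameterError(f"k={self.k} exceeds {X.shape[0]} points")
        if self.method == "kmeans":
            est = KMeans(n_clusters=self.k, n_init=10, random_state=self.random_state)
            self.labels_ = est.fit_predict(X).astype(np.int64)
        elif self.method == "gmm":
            est = GaussianMixture(
                n_components=self.k, random_state=self.random_state, n_init=3
            )
            self.labels_ = est.fit(X).predict(X).astype(np.int64)
        else:
            raise ParameterError(f"unknown baseline method {self.method!r}")
        return self


def _points(embedding) -> np.ndarray:
    if isinstance(embedding, Embedding):
        return embedding.points
    return np.asarray(embedding, dtype=np.float64)


def cluster_hdbscan(embedding, config: ClusterConfig | None = None) -> Labeling:
    config = config or ClusterConfig()
    est = HDBSCANClusterer(
        min_cluster_size=config.min_cluster_size, min_samples=config.min_samples
    ).fit(_points(embedding))
    return Labeling(labels=est.labels_, method="hdbscan")


def cluster_baseline(embedding, config: ClusterConfig | None = None) -> Labeling:
    config = config or ClusterConfig()
    est = BaselineClusterer(
        method=config.baseline_method, k=config.k, random_state=config.seed
    ).fit(_points(embedding))
    return Labeling(labels=est.labels_, method=config.baseline_method)


def select_best_unit(
    labeling: Labeling,
    event_times: np.ndarray,
    gt_times: np.ndarray,
    epsilon: float,
) -> tuple[Optional[int], Metrics]:
    """Return the non-noise cluster best matching a GT unit (max F1).

    Ties break toward the smallest label; if every point is noise, returns
    (None, zero metrics).
    """
    event_times = np.asarray(event_times)
    if event_times.size != len(labeling):
        raise ParameterError("labeling must align with event_times")
    best_label: Optional[int] = None
    best = Metrics.zero()
    for label in labeling.cluster_ids:  # ascending -> ties keep smallest
        times = np.sort(event_times[labeling.labels == label])
        m = f1_against_gt(times, gt_times, epsilon)
        if m.f1 > best.f1:
            best_label, best = int(label), m
    return best_label, best
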