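"""Dimensionality reduction of spike waveforms.

Three embedders share a scikit-learn transformer interface:

* :class:`UMAPEmbedder` — nonlinear neighbor-graph embedding (delegated to
  umap-learn) with the sorting defaults n_components=2, min_dist=0,
  n_neighbors=15;
* :class:`PCAEmbedder` — principal components of the waveform covariance
  (N-1 denominator, mean-centered scores);
* :class:`WaveletEmbedder` — multilevel DWT per waveform with
  Kolmogorov-Smirnov ranking of coefficients against a fitted normal and
  selection of the top-K most non-normal coefficients.

``tune_n_neighbors`` selects the UMAP neighborhood size by maximizing the
KS divergence between the embedding's coordinate distributions and a
normal — the most cluster-structured (least Gaussian) embedding wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pywt
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import ParameterError
from .io import WaveformSet


@dataclass
class Embedding:
    """Low-dimensional representation of a waveform set."""

    points: np.ndarray  # (n_spikes, d)
    method: str
    params: dict = field(default_factory=dict)
    source: Optional[WaveformSet] = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if not np.all(np.isfinite(self.points)):
            raise ParameterError("embedding contains non-finite values")

    @property
    def n_spikes(self) -> int:
        return self.points.shape[0]


@dataclass
class PCAModel:
    """Mean waveform, principal axes (columns) and descending eigenvalues."""

    means: np.ndarray
    components: np.ndarray  # (n_points, n_points), columns are PCs
    eigenvalues: np.ndarray  # descending


@dataclass
class WaveletFeatures:
    """Full DWT coefficient matrix with KS scores and the selected subset."""

    coeffs: np.ndarray  # (n_spikes, n_coeffs)
    ks_scores: np.ndarray
    selected: np.ndarray  # indices ordered by descending KS score
    wavelet: str
    levels: int


def _as_matrix(ws) -> np.ndarray:
    if isinstance(ws, WaveformSet):
        return ws.waves
    return check_array(np.asarray(ws, dtype=np.float64))


def ks_vs_normal(values: np.ndarray) -> float:
    """KS statistic of a sample against a normal with its own mean and SD.

    Degenerate (zero-variance) samples score 0: they carry no
    cluster-separating structure.
    """
    values = np.asarray(values, dtype=np.float64)
    sd = values.std()
    if sd == 0 or values.size < 2:
        return 0.0
    return float(stats.kstest(values, "norm", args=(values.mean(), sd)).statistic)


# ---------------------------------------------------------------------------
# UMAP
# ---------------------------------------------------------------------------

class UMAPEmbedder(TransformerMixin, BaseEstimator):
    """UMAP projection of spike waveforms with spike-sorting defaults.

    Parameters mirror umap-learn; ``min_dist=0`` keeps the embedding's
    density structure maximally faithful for the downstream density-based
    clustering step.
    """

    def __init__(
        self,
        n_neighbors: int = 15,
        min_dist: float = 0.0,
        n_components: int = 2,
        random_state: int = 0,
    ):
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.n_components = n_components
        self.random_state = random_state

    def fit(self, X, y=None):
        self.fit_transform(X, y)
        return self

    def fit_transform(self, X, y=None):
        import umap  # deferred: numba compilation is expensive at import

        X = _as_matrix(X)
        if X.shape[0] <= self.n_neighbors:
            raise ParameterError(
                f"n_spikes={X.shape[0]} must exceed n_neighbors="
                f"{self.n_neighbors}; reduce n_neighbors"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(
                n_neighbors=self.n_neighbors,
                min_dist=self.min_dist,
                n_components=self.n_components,
                random_state=self.random_state,
            )
            pts = reducer.fit_transform(X)
        self.reducer_ = reducer
        self.embedding_ = np.asarray(pts, dtype=np.float64)
        return self.embedding_

    def transform(self, X):
        check_is_fitted(self, "reducer_")
        return np.asarray(self.reducer_.transform(_as_matrix(X)), dtype=np.float64)


def embed_umap(
    ws,
    n_neighbors: int = 15,
    min_dist: float = 0.0,
    n_components: int = 2,
    seed: int = 0,
) -> Embedding:
    est = UMAPEmbedder(
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        n_components=n_components,
        random_state=seed,
    )
    pts = est.fit_transform(ws)
    return Embedding(
        points=pts,
        method="umap",
        params={
            "n_neighbors": n_neighbors,
            "min_dist": min_dist,
            "n_components": n_components,
            "seed": seed,
        },
        source=ws if isinstance(ws, WaveformSet) else None,
    )


def embedding_ks_divergence(points: np.ndarray) -> float:
    """Mean per-dimension KS statistic of an embedding against a normal."""
    points = np.atleast_2d(points)
    return float(np.mean([ks_vs_normal(points[:, d]) for d in range(points.shape[1])]))


def tune_n_neighbors(
    ws,
    grid: Sequence[int],
    seed: int = 0,
    min_dist: float = 0.0,
    n_components: int = 2,
) -> tuple[int, dict[int, float]]:
    """Select n_neighbors by maximal KS divergence from normality.

    Embeds once per grid value (min_dist held at 0) and scores each
    embedding by the mean per-dimension KS statistic against a normal with
    the dimension's sample mean/SD; ties go to the smaller value.
    """
    if not len(grid):
        raise ParameterError("grid must be non-empty")
    X = _as_matrix(ws)
    scores: dict[int, float] = {}
    for nn in grid:
        if nn >= X.shape[0]:
            warnings.warn(f"skipping n_neighbors={nn} >= n_spikes={X.shape[0]}")
            continue
        emb = embed_umap(X, n_neighbors=nn, min_dist=min_dist,
                         n_components=n_components, seed=seed)
        scores[int(nn)] = embedding_ks_divergence(emb.points)
    if not scores:
        raise ParameterError("every grid value was >= n_spikes")
    best = min(sorted(scores), key=lambda nn: (-scores[nn], nn))
    return best, scores


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class PCAEmbedder(TransformerMixin, BaseEstimator):
    """Principal-component scores of waveforms.

    The covariance across waveforms uses the N-1 denominator; scores are
    projections of mean-centered waveforms onto the leading eigenvectors,
    with eigenvalues sorted descending.
    """

    def __init__(self, n_pcs: int = 2):
        self.n_pcs = n_pcs

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if X.shape[0] < 2:
            raise ParameterError("PCA requires at least 2 waveforms")
        if self.n_pcs > X.shape[1]:
            raise ParameterError("n_pcs cannot exceed the number of time points")
        self.mean_ = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        self.eigenvalues_ = np.clip(evals[order], 0.0, None)
        self.components_ = evecs[:, order]
        rank = int(np.sum(self.eigenvalues_ > 1e-12 * max(self.eigenvalues_[0], 1e-300)))
        if self.n_pcs > rank:
            warnings.warn(
                f"n_pcs={self.n_pcs} exceeds covariance rank {rank}; trailing "
                "components have zero variance"
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = _as_matrix(X)
        return (X - self.mean_) @ self.components_[:, : self.n_pcs]

    @property
    def model_(self) -> PCAModel:
        check_is_fitted(self, "components_")
        return PCAModel(
            means=self.mean_, components=self.components_, eigenvalues=self.eigenvalues_
        )


def embed_pca(ws, n_pcs: int = 2) -> tuple[Embedding, PCAModel]:
    est = PCAEmbedder(n_pcs=n_pcs).fit(ws)
    pts = est.transform(ws)
    emb = Embedding(
        points=pts,
        method="pca",
        params={"n_pcs": n_pcs},
        source=ws if isinstance(ws, WaveformSet) else None,
    )
    return emb, est.model_


# ---------------------------------------------------------------------------
# Wavelets
# ---------------------------------------------------------------------------

class WaveletEmbedder(TransformerMixin, BaseEstimator):
    """Top-K most non-normal DWT coefficients as features.

    Each waveform is decomposed by a multilevel DWT; the per-coefficient
    distribution across spikes is scored by its KS statistic against a
    fitted normal, and the K highest-scoring coefficients (the ones most
    likely to be multimodal, hence cluster-separating) form the feature
    vector.
    """

    def __init__(self, wavelet: str = "haar", levels: int = 4, K: int = 6):
        self.wavelet = wavelet
        self.levels = levels
        self.K = K

    @staticmethod
    def _dwt_matrix(X: np.ndarray, wavelet: str, levels: int) -> np.ndarray:
        coeff_list = pywt.wavedec(X, wavelet, level=levels, axis=1)
        return np.concatenate(coeff_list, axis=1)

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if X.shape[1] < 2**self.levels:
            raise ParameterError(
                f"waveform length {X.shape[1]} too short for {self.levels} DWT levels"
            )
        coeffs = self._dwt_matrix(X, self.wavelet, self.levels)
        if self.K > coeffs.shape[1]:
            raise ParameterError(
                f"K={self.K} exceeds the {coeffs.shape[1]} available coefficients"
            )
        scores = np.array([ks_vs_normal(coeffs[:, j]) for j in range(coeffs.shape[1])])
        order = np.argsort(-scores, kind="stable")
        self.ks_scores_ = scores
        self.selected_ = order[: self.K]
        self.n_coeffs_ = coeffs.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_")
        coeffs = self._dwt_matrix(_as_matrix(X), self.wavelet, self.levels)
        return coeffs[:, self.selected_]

    def features_(self, X) -> WaveletFeatures:
        check_is_fitted(self, "selected_")
        coeffs = self._dwt_matrix(_as_matrix(X), self.wavelet, self.levels)
        return WaveletFeatures(
            coeffs=coeffs,
            ks_scores=self.ks_scores_,
            selected=self.selected_,
            wavelet=self.wavelet,
            levels=self.levels,
        )


def embed_wavelet(
    ws, wavelet: str = "haar", levels: int = 4, K: int = 6
) -> tuple[Embedding, WaveletFeatures]:
    est = WaveletEmbedder(wavelet=wavelet, levels=levels, K=K).fit(ws)
    emb = Embedding(
        points=est.transform(ws),
        method="wavelet",
        params={"wavelet": wavelet, "levels": levels, "K": K},
        source=ws if isinstance(ws, WaveformSet) else None,
    )
    return emb, est.features_(ws)
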