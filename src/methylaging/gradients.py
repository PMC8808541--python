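"""Normalized running-median gradients, smoothing, clustering, embedding.

Each marker's running-median track is normalized by its own maximum so that
relative change rates are comparable across markers; the per-year gradient
of the normalized track is then the object clustered with k-means.  A
Savitzky-Golay filter (default window 21, polynomial order 2) smooths the
gradients for reporting/plotting; clustering always uses the raw normalized
gradients.  A t-SNE embedding of the gradients supports choosing the number
of clusters by eye, and a silhouette-based suggestion is computed from the
embedding as an advisory default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "normalize_track",
    "compute_gradient",
    "savgol_smooth",
    "kmeans_cluster",
    "tsne_embed",
    "suggest_k",
    "GradientClusterer",
]


def normalize_track(values, marker_id: str | None = None) -> np.ndarray:
    """Divide a track by its maximum so the largest value becomes 1."""
    v = np.asarray(values, dtype=float)
    peak = np.nanmax(v)
    if not peak > 0:
        name = f" for marker {marker_id!r}" if marker_id else ""
        raise ValueError(f"cannot normalize an all-zero track{name}")
    return v / peak


def compute_gradient(values, years) -> np.ndarray:
    """Finite-difference gradient of a track over its (possibly uneven) year grid.

    Central differences ``(v[i+1] - v[i-1]) / (y[i+1] - y[i-1])`` at interior
    points, one-sided differences at the two ends.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(years, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 points")
    if v.shape != y.shape:
        raise ValueError("values and years must have the same length")
    if np.any(np.diff(y) <= 0):
        raise ValueError("years must be strictly increasing")
    g = np.empty_like(v)
    g[0] = (v[1] - v[0]) / (y[1] - y[0])
    g[-1] = (v[-1] - v[-2]) / (y[-1] - y[-2])
    if v.size > 2:
        g[1:-1] = (v[2:] - v[:-2]) / (y[2:] - y[:-2])
    return g


def savgol_smooth(vector, window: int = 21, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay least-squares smoothing with polynomial edge extension.

    If the vector is shorter than ``window``, the window shrinks to the
    largest valid odd size.  Raises if ``polyorder >= window`` or the vector
    is too short for any valid window.
    """
    v = np.asarray(vector, dtype=float)
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than the window length")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    eff = min(window, v.size if v.size % 2 == 1 else v.size - 1)
    if eff <= polyorder:
        raise ValueError(
            f"vector of length {v.size} is too short for polynomial order {polyorder}"
        )
    return savgol_filter(v, window_length=eff, polyorder=polyorder, mode="interp")


def kmeans_cluster(gradients, k: int, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """k-means labels (1-based) on a markers x years gradient matrix."""
    X = np.asarray(gradients, dtype=float)
    if not 1 <= k <= X.shape[0]:
        raise ValueError(f"k must be between 1 and the number of markers ({X.shape[0]})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(X) + 1


def tsne_embed(gradients, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """2-D t-SNE embedding of the gradient matrix (one point per marker)."""
    X = np.asarray(gradients, dtype=float)
    if X.shape[0] < 5:
        raise ValueError("need at least 5 markers to embed")
    if perplexity >= X.shape[0]:
        raise ValueError("perplexity must be smaller than the number of markers")
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    return tsne.fit_transform(X)


def suggest_k(embedding, k_max: int = 6, seed: int = 0) -> int:
    """Advisory cluster count: the k in 2..k_max maximizing the mean silhouette
    on the embedding, falling back to 1 for degenerate (near-constant) input."""
    X = np.asarray(embedding, dtype=float)
    if X.shape[0] < 3 or np.allclose(X, X[0]):
        return 1
    best_k, best_s = 1, -np.inf
    for k in range(2, min(k_max, X.shape[0] - 1) + 1):
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(X, labels)
        if s > best_s:
            best_k, best_s = k, s
    return best_k


class GradientClusterer(BaseEstimator, ClusterMixin):
    """Cluster markers by the age-gradient of their normalized running medians.

    ``fit`` takes a markers x years running-median table (as produced by the
    running-median stage).  Fitted attributes: ``normalized_``,
    ``gradients_``, ``smoothed_`` (all DataFrames markers x years),
    ``labels_`` (1-based), ``embedding_`` (markers x 2) and ``suggested_k_``.
    The embedding and suggestion are diagnostics; the configured
    ``n_clusters`` is what is applied.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        seed: int = 0,
        n_init: int = 10,
        window: int = 21,
        polyorder: int = 2,
        perplexity: float = 30.0,
        embed: bool = True,
    ):
        self.n_clusters = n_clusters
        self.seed = seed
        self.n_init = n_init
        self.window = window
        self.polyorder = polyorder
        self.perplexity = perplexity
        self.embed = embed

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        years = X.columns.to_numpy(dtype=float)
        norm = np.vstack([normalize_track(X.loc[m].to_numpy(), m) for m in X.index])
        grad = np.vstack([compute_gradient(row, years) for row in norm])
        smooth = np.vstack([savgol_smooth(row, self.window, self.polyorder) for row in grad])
        self.normalized_ = pd.DataFrame(norm, index=X.index, columns=X.columns)
        self.gradients_ = pd.DataFrame(grad, index=X.index, columns=X.columns)
        self.smoothed_ = pd.DataFrame(smooth, index=X.index, columns=X.columns)
        self.labels_ = kmeans_cluster(grad, self.n_clusters, seed=self.seed, n_init=self.n_init)
        if self.embed and X.shape[0] >= 5:
            perp = min(self.perplexity, X.shape[0] - 1)
            self.embedding_ = tsne_embed(grad, seed=self.seed, perplexity=perp)
            self.suggested_k_ = suggest_k(self.embedding_, seed=self.seed)
        else:
            self.embedding_ = None
            self.suggested_k_ = None
        return self

    def summary(self) -> dict:
        """Per-cluster size, dominant gradient sign and mean gradient curve."""
        check_is_fitted(self, "labels_")
        out = {}
        for lbl in np.unique(self.labels_):
            rows = self.gradients_.to_numpy()[self.labels_ == lbl]
            mean_curve = rows.mean(axis=0)
            out[int(lbl)] = {
                "n_markers": int(rows.shape[0]),
                "sign": "positive" if mean_curve.mean() >= 0 else "negative",
                "mean_gradient": mean_curve.tolist(),
            }
        return out
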