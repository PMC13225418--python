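"""Clustering of the learned embedding and agreement scoring.

Spatial domains are obtained by fitting a Gaussian mixture with a shared
full covariance matrix (the mclust-EEE model family) to the final embedding
via EM, with seeded k-means++ initialization.  Agreement with reference
labels is reported as the adjusted Rand index, normalized mutual
information (arithmetic-mean normalization) and Fowlkes-Mallows index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    adjusted_rand_score,
    fowlkes_mallows_score,
    normalized_mutual_info_score,
)
from sklearn.mixture import GaussianMixture

__all__ = [
    "DomainLabels",
    "cluster_embedding",
    "score_ari",
    "score_nmi",
    "score_fmi",
    "score_all",
    "umap_embedding",
]


@dataclass
class DomainLabels:
    labels: np.ndarray
    n_domains: int
    method: str
    posterior: np.ndarray | None = None


def cluster_embedding(E_final: np.ndarray, n_domains: int, seed: int = 100) -> DomainLabels:
    """EM Gaussian-mixture clustering with shared full covariance.

    Responsibilities are initialized from a seeded k-means solution (itself
    k-means++ seeded); five EM starts are run and the highest-likelihood fit
    kept, each for at most 500 iterations to a 1e-6 log-likelihood
    tolerance.  Hard labels are the posterior argmax.  If EM degenerates,
    one re-initialization from a shifted seed is attempted before raising.
    """
    E_final = np.asarray(E_final, dtype=np.float64)
    if n_domains < 2:
        raise ValueError("n_domains must be >= 2")
    if not np.all(np.isfinite(E_final)):
        raise ValueError("embedding contains non-finite values")

    def fit(s):
        gm = GaussianMixture(
            n_components=n_domains,
            covariance_type="tied",
            max_iter=500,
            tol=1e-6,
            n_init=5,
            init_params="kmeans",
            random_state=s,
            reg_covar=1e-6,
        )
        post = gm.fit(E_final).predict_proba(E_final)
        return gm, post

    try:
        gm, post = fit(seed)
    except ValueError:
        warnings.warn("EM degenerate; re-initializing from a shifted seed")
        gm, post = fit(seed + 1)
    labels = post.argmax(axis=1)
    if len(np.unique(labels)) < n_domains:
        warnings.warn("some mixture components claimed no spots")
    return DomainLabels(
        labels=labels, n_domains=n_domains, method="gmm-em-tied", posterior=post
    )


def _check_pair(a, b):
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    return a, b


def score_ari(true_labels, pred_labels) -> float:
    """Adjusted Rand index in [-1, 1]."""
    a, b = _check_pair(true_labels, pred_labels)
    return float(adjusted_rand_score(a, b))


def score_nmi(true_labels, pred_labels) -> float:
    """Normalized mutual information (arithmetic-mean normalization) in [0, 1]."""
    a, b = _check_pair(true_labels, pred_labels)
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def score_fmi(true_labels, pred_labels) -> float:
    """Fowlkes-Mallows index TP / sqrt((TP+FP)(TP+FN)) over spot pairs."""
    a, b = _check_pair(true_labels, pred_labels)
    val = float(fowlkes_mallows_score(a, b))
    if val == 0.0:
        warnings.warn("no co-clustered pairs shared between the labelings")
    return val


def score_all(true_labels, pred_labels) -> dict:
    return {
        "ari": score_ari(true_labels, pred_labels),
        "nmi": score_nmi(true_labels, pred_labels),
        "fmi": score_fmi(true_labels, pred_labels),
    }


def umap_embedding(E_final: np.ndarray, seed: int = 100, **kwargs) -> np.ndarray:
    """Convenience 2-D UMAP of the embedding (visualization only, untested)."""
    import umap

    return umap.UMAP(random_state=seed, **kwargs).fit_transform(E_final)
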