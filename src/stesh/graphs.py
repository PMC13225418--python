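"""Construction of the spatial, expression and morphological adjacency graphs.

Three binary n-by-n adjacencies are built over the spots:

* ``A_s`` — spatial: spots closer than a radius ``r`` (strict inequality) are
  neighbors.  The diagonal is 1 automatically (distance 0 < r).
* ``A_f`` — expression: k-nearest-neighbor graph under cosine similarity of
  the normalized expression rows.
* ``A_m`` — morphological: k-nearest-neighbor graph under Pearson correlation
  of the latent image-patch features.

Each adjacency is symmetrically normalized, A~ = D^{-1/2} A D^{-1/2} with D
the degree matrix (self-loops guaranteed), which is the propagation operator
used by every GCN branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sparse
from scipy.spatial.distance import cdist

__all__ = [
    "GraphBundle",
    "spatial_adjacency",
    "cosine_similarity",
    "pearson_similarity",
    "knn_adjacency",
    "symmetric_normalize",
    "default_radius",
    "build_graph_bundle",
]


@dataclass
class GraphBundle:
    """The three adjacencies, their normalizations and per-spot neighbor sets."""

    A_s: sparse.csr_matrix
    A_f: sparse.csr_matrix
    A_s_norm: sparse.csr_matrix
    A_f_norm: sparse.csr_matrix
    A_m: sparse.csr_matrix | None = None
    A_m_norm: sparse.csr_matrix | None = None
    radius_r: float = 0.0
    k_expr: int = 0
    k_morph: int = 0
    neighbor_sets: dict = field(default_factory=dict)

    @property
    def n_spots(self) -> int:
        return self.A_s.shape[0]

    @property
    def has_morphology(self) -> bool:
        return self.A_m is not None


def spatial_adjacency(coords: np.ndarray, r: float) -> sparse.csr_matrix:
    """Binary adjacency: A[i, j] = 1 iff Euclidean distance d(i, j) < r.

    The inequality is strict, so spots exactly at distance ``r`` are not
    neighbors; the diagonal is always 1.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords must be finite")
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r}")
    d = cdist(coords, coords)
    a = (d < r).astype(np.float64)
    if np.any(a.sum(axis=1) <= 1):
        warnings.warn("some spots have no spatial neighbor besides themselves")
    return sparse.csr_matrix(a)


def cosine_similarity(X: np.ndarray) -> np.ndarray:
    """Row-wise cosine similarity x_i . x_j / (|x_i| |x_j|); zero rows map to 0."""
    X = np.asarray(X, dtype=np.float64)
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero rows; their similarities set to 0")
    safe = np.where(zero, 1.0, norms)
    Xn = X / safe[:, None]
    S = Xn @ Xn.T
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    np.clip(S, -1.0, 1.0, out=S)
    np.fill_diagonal(S, np.where(zero, 0.0, 1.0))
    return S


def pearson_similarity(M: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of the feature matrix; constant rows map to 0."""
    M = np.asarray(M, dtype=np.float64)
    if M.shape[1] < 2:
        raise ValueError("Pearson correlation needs feature dimension >= 2")
    centered = M - M.mean(axis=1, keepdims=True)
    sd = np.linalg.norm(centered, axis=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance rows; similarities set to 0")
    safe = np.where(zero, 1.0, sd)
    Cn = centered / safe[:, None]
    S = Cn @ Cn.T
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    np.clip(S, -1.0, 1.0, out=S)
    np.fill_diagonal(S, np.where(zero, 0.0, 1.0))
    return S


def knn_adjacency(S: np.ndarray, k: int, symmetrize: bool = True) -> sparse.csr_matrix:
    """Top-k neighbor graph from a similarity matrix.

    Self is excluded from the ranking; ties break toward the smaller index;
    the matrix is then OR-symmetrized (i ~ j if either selects the other)
    unless ``symmetrize=False``, and the diagonal is set to 1.
    """
    S = np.asarray(S, dtype=np.float64)
    n = S.shape[0]
    if not (1 <= k < n):
        raise ValueError(f"k must satisfy 1 <= k < n={n}, got {k}")
    A = np.zeros((n, n))
    masked = S.copy()
    np.fill_diagonal(masked, -np.inf)
    # stable sort on (-similarity, index) gives deterministic tie-breaking
    order = np.argsort(-masked, axis=1, kind="stable")
    rows = np.repeat(np.arange(n), k)
    A[rows, order[:, :k].ravel()] = 1.0
    if symmetrize:
        A = np.maximum(A, A.T)
    np.fill_diagonal(A, 1.0)
    return sparse.csr_matrix(A)


def symmetric_normalize(A) -> sparse.csr_matrix:
    """A~ = D^{-1/2} A D^{-1/2} with D the degree matrix of A."""
    A = sparse.csr_matrix(A, dtype=np.float64)
    if A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if A.min() < 0:
        raise ValueError("adjacency must be nonnegative")
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg == 0):
        raise ValueError("zero-degree row: insert self-loops before normalizing")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    D = sparse.diags(d_inv_sqrt)
    return (D @ A @ D).tocsr()


def default_radius(coords: np.ndarray, factor: float = 1.3) -> float:
    """``factor`` times the minimum nonzero pairwise spot distance.

    On a Visium-style hexagonal array this captures the six direct neighbors.
    """
    d = cdist(coords, coords)
    nz = d[d > 0]
    if nz.size == 0:
        raise ValueError("all spots coincide; cannot infer a radius")
    return factor * float(nz.min())


def _neighbor_sets(A: sparse.csr_matrix) -> list[np.ndarray]:
    """Off-diagonal neighbor indices per spot (for the regularization loss)."""
    A = A.tocsr()
    out = []
    for i in range(A.shape[0]):
        cols = A.indices[A.indptr[i]:A.indptr[i + 1]]
        out.append(cols[cols != i].copy())
    return out


def build_graph_bundle(
    X: np.ndarray,
    coords: np.ndarray,
    M: np.ndarray | None = None,
    *,
    r: float | None = None,
    k_expr: int = 10,
    k_morph: int = 10,
    symmetrize_knn: bool = True,
) -> GraphBundle:
    """Build all adjacencies and their normalizations from row-aligned inputs.

    When ``M`` is None (no histology image) the morphological graph is
    omitted and downstream components run in image-free mode.
    """
    X = np.asarray(X)
    coords = np.asarray(coords)
    if X.shape[0] != coords.shape[0]:
        raise ValueError("X and coords must have the same number of rows")
    if M is not None and np.asarray(M).shape[0] != X.shape[0]:
        raise ValueError("M must be row-aligned with X")
    if r is None:
        r = default_radius(coords)
    A_s = spatial_adjacency(coords, r)
    A_f = knn_adjacency(cosine_similarity(X), k_expr, symmetrize=symmetrize_knn)
    A_m = None
    A_m_norm = None
    neighbor_sets = {"spatial": _neighbor_sets(A_s), "expression": _neighbor_sets(A_f)}
    if M is not None:
        A_m = knn_adjacency(pearson_similarity(M), k_morph, symmetrize=symmetrize_knn)
        A_m_norm = symmetric_normalize(A_m)
        neighbor_sets["morphology"] = _neighbor_sets(A_m)
    return GraphBundle(
        A_s=A_s,
        A_f=A_f,
        A_m=A_m,
        A_s_norm=symmetric_normalize(A_s),
        A_f_norm=symmetric_normalize(A_f),
        A_m_norm=A_m_norm,
        radius_r=float(r),
        k_expr=k_expr,
        k_morph=k_morph if M is not None else 0,
        neighbor_sets=neighbor_sets,
    )
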