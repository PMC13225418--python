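"""Multi-view graph convolutional autoencoder: encoder, fusion, decoder, losses.

Architecture
------------
Three view-specific two-layer GCN branches (spatial, expression,
morphological) each propagate the expression matrix X over their own
normalized adjacency, E(l+1) = ReLU(A~ E(l) W(l)), with layer widths
input -> 128 -> 64 and a linear (activation-free) final layer.  A fourth,
collaborative branch applies one shared weight set to all three graphs; its
per-graph outputs E_cs, E_cf, E_cm are averaged into the collaborative
embedding E_c and pulled together by a consistency loss.  An attention
module scores the four view embeddings per spot (two-layer tanh projection,
hidden width 16, softmax over views), forms the convex combination E_fusion
and projects it linearly to E_final.  A negative-binomial decoder
reconstructs X from E_final via a linear + batch-norm + ReLU hidden layer
and two positive heads for the mean mu and dispersion theta.

Losses: NB negative log-likelihood, cross-view consistency, and a
graph-structure regularizer contrasting cosine similarities of E_final over
spatial/morphological neighbors vs sampled non-neighbors; total
L = alpha * L_nb + beta * L_con + gamma * L_reg.

All public operations accept either plain NumPy arrays (for direct use and
oracle testing) or autodiff tensors (used during training).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sparse
from scipy.special import gammaln as _np_gammaln

from .autodiff import Tensor, glorot_uniform, spmm
from .graphs import GraphBundle

__all__ = [
    "ModelConfig",
    "EncoderParams",
    "ViewEmbeddings",
    "FusionResult",
    "NBDecoderOutput",
    "LossBundle",
    "STESHModel",
    "gcn_layer",
    "encode",
    "attention_fuse",
    "nb_decode",
    "nb_neg_loglik",
    "consistency_loss",
    "regularization_loss",
    "total_loss",
    "sample_negative_masks",
]

VIEW_ORDER = ("s", "f", "m", "c")
_EPS = 1e-8


# --------------------------------------------------------------------------
# generic numerics: every op below works on ndarray and on Tensor
# --------------------------------------------------------------------------

def _is_t(x) -> bool:
    return isinstance(x, Tensor)


def _val(x) -> np.ndarray:
    return x.data if _is_t(x) else np.asarray(x)


def _relu(x):
    return x.relu() if _is_t(x) else np.maximum(x, 0)


def _tanh(x):
    return x.tanh() if _is_t(x) else np.tanh(x)


def _exp(x):
    return x.exp() if _is_t(x) else np.exp(x)


def _log(x):
    return x.log() if _is_t(x) else np.log(x)


def _sqrt(x):
    return x.sqrt() if _is_t(x) else np.sqrt(x)


def _softplus(x):
    if _is_t(x):
        return x.softplus()
    return np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))


def _gammaln(x):
    return x.gammaln() if _is_t(x) else _np_gammaln(x)


def _clip(x, lo, hi):
    return x.clip(lo, hi) if _is_t(x) else np.clip(x, lo, hi)


def _sum(x, axis=None, keepdims=False):
    return x.sum(axis=axis, keepdims=keepdims)


def _mean_all(x):
    return x.mean() if _is_t(x) else float(np.mean(x))


def _propagate(A, E):
    """A @ E with A a constant (possibly sparse) adjacency."""
    if _is_t(E):
        return spmm(A, E) if sparse.issparse(A) else Tensor(A) @ E
    return A @ _val(E) if sparse.issparse(A) else np.asarray(A) @ np.asarray(E)


def _row_normalize(E):
    """L2-normalize rows (epsilon-guarded for zero rows)."""
    sq = _sum(E * E, axis=1, keepdims=True)
    return E / _sqrt(sq + _EPS)


# --------------------------------------------------------------------------
# configuration and containers
# --------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture and loss hyperparameters."""

    hidden_dim: int = 128
    latent_dim: int = 64
    attn_hidden: int = 16
    decoder_hidden: int = 128
    alpha: float = 1.0
    beta: float = 10.0
    gamma: float = 0.1
    final_relu: bool = False  # activation after the second GCN layer
    collab_weights: str = "shared"  # or "tied_to_views"
    consistency_mode: str = "similarity"  # or "embedding_space"
    negative_mode: str = "sampled"  # or "full"
    nb_target: str = "model_input"  # or "raw_counts"


@dataclass
class EncoderParams:
    """Per-view and collaborative GCN weights (no biases)."""

    W_s: tuple  # (W1: input x hidden, W2: hidden x latent)
    W_f: tuple
    W_m: tuple | None
    W_c: tuple


@dataclass
class ViewEmbeddings:
    E_s: object
    E_f: object
    E_c: object
    E_cs: object
    E_cf: object
    E_m: object = None
    E_cm: object = None

    def views(self) -> dict:
        out = {"s": self.E_s, "f": self.E_f}
        if self.E_m is not None:
            out["m"] = self.E_m
        out["c"] = self.E_c
        return out

    def collaborative(self) -> list:
        out = [self.E_cs, self.E_cf]
        if self.E_cm is not None:
            out.insert(0, self.E_cm)
        return out


@dataclass
class FusionResult:
    omega_hat: np.ndarray  # (n, n_views) raw scores
    omega: np.ndarray  # (n, n_views) softmax weights
    E_fusion: object
    E_final: object
    view_names: tuple = VIEW_ORDER


@dataclass
class NBDecoderOutput:
    mu: object
    theta: object


@dataclass
class LossBundle:
    L_nb: float
    L_con: float
    L_reg_m: float
    L_reg_s: float
    L_reg: float
    L_total: float
    alpha: float
    beta: float
    gamma: float


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def gcn_layer(A_norm, E, W, activate: bool = True):
    """One propagation step: ReLU(A~ E W), or A~ E W when ``activate`` is off."""
    out = _propagate(A_norm, E) @ W
    out = _relu(out) if activate else out
    if not np.all(np.isfinite(_val(out))):
        raise FloatingPointError("non-finite values produced by GCN layer")
    return out


def propagate_input(bundle: GraphBundle, X) -> dict:
    """Precompute the constant first-layer propagation A~ X per graph.

    X and the adjacencies never change during training, so these products
    can be shared across every epoch and branch.
    """
    cache = {
        "s": _propagate(bundle.A_s_norm, X),
        "f": _propagate(bundle.A_f_norm, X),
    }
    if bundle.has_morphology:
        cache["m"] = _propagate(bundle.A_m_norm, X)
    return cache


def encode(X, bundle: GraphBundle, params: EncoderParams,
           final_relu: bool = False, ax_cache: dict | None = None) -> ViewEmbeddings:
    """Run the view-specific and collaborative branches.

    The collaborative weights are applied to every available graph; the
    collaborative embedding is their arithmetic mean.  Without a
    morphological graph the model runs in image-free mode over two graphs.
    ``ax_cache`` (from :func:`propagate_input`) skips the recomputation of
    the constant A~ X products; results are identical with or without it.
    """
    if ax_cache is None:
        ax_cache = propagate_input(bundle, X)

    def branch(A, ax, W):
        h = _relu(ax @ W[0])
        return gcn_layer(A, h, W[1], activate=final_relu)

    E_s = branch(bundle.A_s_norm, ax_cache["s"], params.W_s)
    E_f = branch(bundle.A_f_norm, ax_cache["f"], params.W_f)
    E_cs = branch(bundle.A_s_norm, ax_cache["s"], params.W_c)
    E_cf = branch(bundle.A_f_norm, ax_cache["f"], params.W_c)
    E_m = E_cm = None
    if bundle.has_morphology:
        if params.W_m is None:
            raise ValueError("graph bundle has morphology but params.W_m is None")
        E_m = branch(bundle.A_m_norm, ax_cache["m"], params.W_m)
        E_cm = branch(bundle.A_m_norm, ax_cache["m"], params.W_c)
        E_c = (E_cm + E_cs + E_cf) * (1.0 / 3.0)
    else:
        E_c = (E_cs + E_cf) * 0.5
    return ViewEmbeddings(E_s=E_s, E_f=E_f, E_m=E_m, E_c=E_c,
                          E_cs=E_cs, E_cf=E_cf, E_cm=E_cm)


def attention_fuse(embeddings: dict, W1, b1, W2, W_linear, b_linear) -> FusionResult:
    """Score each view per spot, softmax over views, fuse, project.

    omega_hat_v = W2 tanh(W1 E_v + b1) per spot; omega = softmax over views;
    E_fusion = sum_v omega_v E_v; E_final = E_fusion W_linear + b_linear.
    """
    names = [v for v in VIEW_ORDER if v in embeddings]
    if len(names) < 2:
        raise ValueError("attention fusion needs at least two views")
    scores = {}
    for v in names:
        E = embeddings[v]
        scores[v] = _tanh(E @ W1 + b1) @ W2
    raw = np.column_stack([_val(scores[v]).ravel() for v in names])
    # stabilized softmax over the view axis; the max is a constant shift
    m = raw.max(axis=1, keepdims=True)
    exps = {v: _exp(scores[v] - m) for v in names}
    denom = exps[names[0]]
    for v in names[1:]:
        denom = denom + exps[v]
    E_fusion = None
    omegas = {}
    for v in names:
        w = exps[v] / denom  # (n, 1)
        omegas[v] = _val(w).ravel()
        term = w * embeddings[v]
        E_fusion = term if E_fusion is None else E_fusion + term
    E_final = E_fusion @ W_linear + b_linear
    return FusionResult(
        omega_hat=raw,
        omega=np.column_stack([omegas[v] for v in names]),
        E_fusion=E_fusion,
        E_final=E_final,
        view_names=tuple(names),
    )


def nb_decode(E_final, params: dict, bn_eps: float = 1e-5,
              positivity_eps: float = 1e-4) -> NBDecoderOutput:
    """Decode E_final into positive NB mean and dispersion matrices.

    hidden = ReLU(BatchNorm(Linear(E_final))); mu and theta come from two
    linear heads mapped through softplus + epsilon, with theta clamped to
    [1e-4, 1e4].  Batch normalization uses full-batch statistics, which for
    whole-graph training coincide with population statistics.
    """
    h = E_final @ params["W_h"] + params["b_h"]
    mu_b = h.mean(axis=0, keepdims=True)
    centered = h - mu_b
    var = (centered * centered).mean(axis=0, keepdims=True)
    h = centered / _sqrt(var + bn_eps) * params["bn_gamma"] + params["bn_beta"]
    h = _relu(h)
    mu = _softplus(h @ params["W_mu"] + params["b_mu"]) + positivity_eps
    theta = _clip(
        _softplus(h @ params["W_theta"] + params["b_theta"]) + positivity_eps,
        1e-4, 1e4,
    )
    if not (np.all(np.isfinite(_val(mu))) and np.all(np.isfinite(_val(theta)))):
        raise FloatingPointError("non-finite mu/theta from the NB decoder")
    return NBDecoderOutput(mu=mu, theta=theta)


def nb_neg_loglik(X, mu, theta):
    """Mean negative log-likelihood of X under NB(mu, theta).

    log f_NB = lnG(X+theta) - lnG(X+1) - lnG(theta)
             + theta ln(theta/(theta+mu)) + X ln(mu/(mu+theta));
    X may be real-valued (the gamma function generalizes the factorial).
    """
    if np.any(_val(mu) <= 0) or np.any(_val(theta) <= 0):
        raise ValueError("mu and theta must be strictly positive")
    Xc = _val(X)
    if np.any(Xc < 0):
        raise ValueError("X must be nonnegative")
    ll = (
        _gammaln(Xc + theta)
        - _np_gammaln(Xc + 1.0)
        - _gammaln(theta)
        + theta * _log(theta / (theta + mu))
        + Xc * _log(mu / (mu + theta))
    )
    return -_mean_all(ll) if not _is_t(ll) else -ll.mean()


def consistency_loss(collab_embeddings: list, mode: str = "similarity"):
    """Cross-view consistency over the collaborative embeddings.

    ``similarity`` (default): row-normalize each embedding, form its spot
    pairwise-similarity matrix K = E~ E~^T, and sum squared Frobenius
    differences over all view pairs, scaled by 1/n^2.  ``embedding_space``
    evaluates the squared differences on the normalized embeddings directly
    (scaled by 1/(n d)).
    """
    if len(collab_embeddings) < 2:
        return 0.0
    normed = [_row_normalize(E) for E in collab_embeddings]
    n = _val(normed[0]).shape[0]
    loss = None
    if mode == "similarity":
        # ||K_a - K_b||_F^2 with K = E~ E~^T reduces to Gram matrices in the
        # latent dimension: tr(K_a K_b) = ||E~_a^T E~_b||_F^2, so no n x n
        # matrix is ever formed.
        scale = 1.0 / (n * n)
        grams = {}

        def gram_sq(i, j):
            if (i, j) not in grams:
                G = normed[i].T @ normed[j]
                grams[(i, j)] = _sum(G * G)
            return grams[(i, j)]

        for i in range(len(normed)):
            for j in range(i + 1, len(normed)):
                term = (gram_sq(i, i) - 2.0 * gram_sq(i, j) + gram_sq(j, j)) * scale
                loss = term if loss is None else loss + term
    elif mode == "embedding_space":
        scale = 1.0 / (n * _val(normed[0]).shape[1])
        for i in range(len(normed)):
            for j in range(i + 1, len(normed)):
                diff = normed[i] - normed[j]
                term = _sum(diff * diff) * scale
                loss = term if loss is None else loss + term
    else:
        raise ValueError(f"unknown consistency mode {mode!r}")
    return loss


def sample_negative_masks(
    neighbor_sets: dict,
    n: int,
    rng: np.random.Generator,
    mode: str = "sampled",
) -> dict:
    """Positive/negative index masks for the regularization loss.

    For every node the positive set is its graph neighborhood; negatives are
    ``|N_i|`` uniformly sampled non-neighbors (``sampled``) or the full
    complement (``full``).  Returns {view: (P, Q)} dense 0/1 masks.
    """
    masks = {}
    for view in ("spatial", "morphology"):
        if view not in neighbor_sets:
            continue
        sets = neighbor_sets[view]
        P = np.zeros((n, n))
        Q = np.zeros((n, n))
        for i, nbrs in enumerate(sets):
            P[i, nbrs] = 1.0
            non = np.flatnonzero((P[i] == 0) & (np.arange(n) != i))
            if non.size == 0:
                continue
            if mode == "full":
                Q[i, non] = 1.0
            else:
                take = min(len(nbrs), non.size)
                if take > 0:
                    Q[i, rng.choice(non, size=take, replace=False)] = 1.0
        masks[view] = (P, Q)
    return masks


def mask_indices_one(P: np.ndarray, Q: np.ndarray) -> tuple:
    """Dense 0/1 positive/negative masks -> (pos_rows, pos_cols, neg_rows, neg_cols)."""
    pr, pc = np.nonzero(P)
    qr, qc = np.nonzero(Q)
    return pr, pc, qr, qc


def regularization_loss(E_final, masks: dict):
    """Graph-structure regularizer on cosine similarities of E_final.

    For each graph, positives (neighbors) are pushed toward high similarity
    and negatives toward low similarity through a logistic score:
    L = -[sum_P log sigma(mat) + sum_Q log(1 - sigma(mat))] / (|P| + |Q|),
    with mat the row-cosine-similarity matrix of E_final.  ``masks`` maps a
    view to either dense (P, Q) 0/1 matrices or precomputed index arrays
    (pos_rows, pos_cols, neg_rows, neg_cols).  Returns
    (L_reg_m, L_reg_s, L_reg) where L_reg averages the available graphs.
    """
    En = _row_normalize(E_final)
    mat = En @ En.T
    losses = {}
    for view, spec in masks.items():
        pr, pc, qr, qc = spec if len(spec) == 4 else mask_indices_one(*spec)
        total = pr.size + qr.size
        if total == 0:
            losses[view] = 0.0
            continue
        m_pos = mat.take_pairs(pr, pc) if _is_t(mat) else mat[pr, pc]
        m_neg = mat.take_pairs(qr, qc) if _is_t(mat) else mat[qr, qc]
        # -log sigma(x) = softplus(-x); -log(1 - sigma(x)) = softplus(x)
        losses[view] = (_sum(_softplus(-m_pos)) + _sum(_softplus(m_neg))) * (1.0 / total)
    L_s = losses.get("spatial", 0.0)
    L_m = losses.get("morphology", None)
    if L_m is None:
        return 0.0, L_s, L_s
    return L_m, L_s, (L_m + L_s) * 0.5


def total_loss(l_nb, l_con, l_reg, alpha: float = 1.0, beta: float = 10.0,
               gamma: float = 0.1):
    """L = alpha L_nb + beta L_con + gamma L_reg."""
    if alpha < 0 or beta < 0 or gamma < 0:
        raise ValueError("loss weights must be nonnegative")
    return alpha * l_nb + beta * l_con + gamma * l_reg


# --------------------------------------------------------------------------
# trainable model
# --------------------------------------------------------------------------

class STESHModel:
    """The full trainable model: parameters plus forward/loss evaluation."""

    def __init__(self, n_genes: int, cfg: ModelConfig, rng: np.random.Generator,
                 has_morphology: bool = True, dtype=np.float64):
        self.cfg = cfg
        self.has_morphology = has_morphology
        d_in, d_h, d_z = n_genes, cfg.hidden_dim, cfg.latent_dim

        def pair():
            return (
                Tensor(glorot_uniform(rng, d_in, d_h, dtype), requires_grad=True),
                Tensor(glorot_uniform(rng, d_h, d_z, dtype), requires_grad=True),
            )

        self.W_s = pair()
        self.W_f = pair()
        self.W_m = pair() if has_morphology else None
        self.W_c = pair()
        if cfg.collab_weights == "tied_to_views":
            # collaborative branch reuses the view weights on each graph
            self.W_c = None
        a_h = cfg.attn_hidden
        self.attn = {
            "W1": Tensor(glorot_uniform(rng, d_z, a_h, dtype), requires_grad=True),
            "b1": Tensor(np.zeros(a_h, dtype=dtype), requires_grad=True),
            "W2": Tensor(glorot_uniform(rng, a_h, 1, dtype), requires_grad=True),
            "W_linear": Tensor(glorot_uniform(rng, d_z, d_z, dtype), requires_grad=True),
            "b_linear": Tensor(np.zeros(d_z, dtype=dtype), requires_grad=True),
        }
        dh = cfg.decoder_hidden
        self.decoder = {
            "W_h": Tensor(glorot_uniform(rng, d_z, dh, dtype), requires_grad=True),
            "b_h": Tensor(np.zeros(dh, dtype=dtype), requires_grad=True),
            "bn_gamma": Tensor(np.ones(dh, dtype=dtype), requires_grad=True),
            "bn_beta": Tensor(np.zeros(dh, dtype=dtype), requires_grad=True),
            "W_mu": Tensor(glorot_uniform(rng, dh, d_in, dtype), requires_grad=True),
            "b_mu": Tensor(np.zeros(d_in, dtype=dtype), requires_grad=True),
            "W_theta": Tensor(glorot_uniform(rng, dh, d_in, dtype), requires_grad=True),
            "b_theta": Tensor(np.zeros(d_in, dtype=dtype), requires_grad=True),
        }

    # -- parameters -------------------------------------------------------
    def parameters(self) -> list:
        out = []
        for pair in (self.W_s, self.W_f, self.W_m, self.W_c):
            if pair is not None:
                out.extend(pair)
        out.extend(self.attn.values())
        out.extend(self.decoder.values())
        return out

    def encoder_params(self) -> EncoderParams:
        if self.cfg.collab_weights == "tied_to_views":
            raise NotImplementedError(
                "tied_to_views reuses view weights; use encode_tied()"
            )
        return EncoderParams(W_s=self.W_s, W_f=self.W_f, W_m=self.W_m, W_c=self.W_c)

    # -- forward ----------------------------------------------------------
    def forward(self, X, bundle: GraphBundle, ax_cache: dict | None = None):
        emb = encode(X, bundle, self.encoder_params(),
                     final_relu=self.cfg.final_relu, ax_cache=ax_cache)
        fusion = attention_fuse(
            emb.views(),
            self.attn["W1"], self.attn["b1"], self.attn["W2"],
            self.attn["W_linear"], self.attn["b_linear"],
        )
        dec = nb_decode(fusion.E_final, self.decoder)
        return emb, fusion, dec

    def loss(self, X_target, emb: ViewEmbeddings, fusion: FusionResult,
             dec: NBDecoderOutput, masks: dict):
        cfg = self.cfg
        l_nb = nb_neg_loglik(X_target, dec.mu, dec.theta)
        l_con = consistency_loss(emb.collaborative(), mode=cfg.consistency_mode)
        l_m, l_s, l_reg = regularization_loss(fusion.E_final, masks)
        l_tot = total_loss(l_nb, l_con, l_reg, cfg.alpha, cfg.beta, cfg.gamma)
        bundle = LossBundle(
            L_nb=float(_val(l_nb)),
            L_con=float(_val(l_con)),
            L_reg_m=float(_val(l_m)),
            L_reg_s=float(_val(l_s)),
            L_reg=float(_val(l_reg)),
            L_total=float(_val(l_tot)),
            alpha=cfg.alpha, beta=cfg.beta, gamma=cfg.gamma,
        )
        return l_tot, bundle
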