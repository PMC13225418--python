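"""Encoder, attention, NB decoder and loss terms against independent oracles."""

import numpy as np
import pytest
import scipy.sparse as sparse
from scipy.special import gammaln
from scipy.stats import nbinom, poisson

from stesh.autodiff import Tensor
from stesh.graphs import GraphBundle, build_graph_bundle, symmetric_normalize
from stesh.model import (
    EncoderParams,
    ModelConfig,
    STESHModel,
    attention_fuse,
    consistency_loss,
    encode,
    gcn_layer,
    nb_decode,
    nb_neg_loglik,
    regularization_loss,
    sample_negative_masks,
    total_loss,
)


def identity_bundle(n, with_morph=True):
    I = sparse.identity(n, format="csr")
    return GraphBundle(
        A_s=I, A_f=I, A_m=I if with_morph else None,
        A_s_norm=I, A_f_norm=I, A_m_norm=I if with_morph else None,
        neighbor_sets={"spatial": [np.array([], dtype=int)] * n,
                       "expression": [np.array([], dtype=int)] * n},
    )


class TestGcnLayer:
    def test_identity_propagation(self, rng):
        E = rng.uniform(0, 1, size=(6, 4))
        out = gcn_layer(np.eye(6), E, np.eye(4))
        np.testing.assert_allclose(out, E)

    def test_relu_zeroes_nonpositive(self, rng):
        E = -rng.uniform(0.1, 1, size=(5, 3))
        A = symmetric_normalize(np.ones((5, 5))).toarray()
        out = gcn_layer(A, E, np.eye(3))
        np.testing.assert_array_equal(out, np.zeros((5, 3)))

    def test_matches_dense_oracle(self, rng):
        A = symmetric_normalize(
            np.maximum((rng.random((5, 5)) < 0.5), np.eye(5, dtype=bool)).astype(float)
        )
        E = rng.normal(size=(5, 7))
        W = rng.normal(size=(7, 3))
        out = gcn_layer(A, E, W)
        oracle = np.maximum(A.toarray() @ E @ W, 0)
        np.testing.assert_allclose(out, oracle, rtol=1e-6, atol=1e-9)


class TestEncode:
    def _params(self, rng, d_in, tied=False):
        def pair():
            return (rng.normal(size=(d_in, 8)), rng.normal(size=(8, 4)))

        shared = pair()
        if tied:
            return EncoderParams(W_s=shared, W_f=shared, W_m=shared, W_c=shared)
        return EncoderParams(W_s=pair(), W_f=pair(), W_m=pair(), W_c=pair())

    def test_identical_graphs_and_weights_collapse_views(self, rng):
        X = rng.uniform(0, 1, size=(6, 5))
        params = self._params(rng, 5, tied=True)
        emb = encode(X, identity_bundle(6), params)
        np.testing.assert_allclose(emb.E_s, emb.E_f)
        np.testing.assert_allclose(emb.E_s, emb.E_m)
        np.testing.assert_allclose(emb.E_s, emb.E_c)

    def test_collaborative_embedding_is_exact_mean(self, rng):
        X = rng.uniform(0, 1, size=(10, 5))
        b = build_graph_bundle(
            X, rng.uniform(0, 5, size=(10, 2)), rng.normal(size=(10, 4)),
            r=2.0, k_expr=3, k_morph=3,
        )
        emb = encode(X, b, self._params(rng, 5))
        np.testing.assert_allclose(
            emb.E_c, (emb.E_cm + emb.E_cs + emb.E_cf) / 3.0, rtol=1e-12
        )

    def test_shapes(self, rng):
        X = rng.uniform(0, 1, size=(12, 9))
        b = build_graph_bundle(
            X, rng.uniform(0, 5, size=(12, 2)), rng.normal(size=(12, 4)),
            r=2.0, k_expr=3, k_morph=3,
        )
        emb = encode(X, b, self._params(rng, 9))
        for E in (emb.E_s, emb.E_f, emb.E_m, emb.E_cs, emb.E_cf, emb.E_cm, emb.E_c):
            assert E.shape == (12, 4)

    def test_image_free_mode_averages_two_branches(self, rng):
        X = rng.uniform(0, 1, size=(10, 5))
        b = build_graph_bundle(X, rng.uniform(0, 5, size=(10, 2)), None,
                               r=2.0, k_expr=3)
        p = self._params(rng, 5)
        emb = encode(X, b, p)
        assert emb.E_m is None and emb.E_cm is None
        np.testing.assert_allclose(emb.E_c, (emb.E_cs + emb.E_cf) / 2.0, rtol=1e-12)

    def test_cache_path_is_bitwise_identical(self, rng):
        from stesh.model import propagate_input

        X = rng.uniform(0, 1, size=(10, 5))
        b = build_graph_bundle(X, rng.uniform(0, 5, size=(10, 2)), None,
                               r=2.0, k_expr=3)
        p = self._params(rng, 5)
        emb1 = encode(X, b, p)
        emb2 = encode(X, b, p, ax_cache=propagate_input(b, X))
        np.testing.assert_array_equal(emb1.E_c, emb2.E_c)


class TestAttention:
    def _params(self, rng, d=4, h=3):
        return dict(
            W1=rng.normal(size=(d, h)), b1=rng.normal(size=h),
            W2=rng.normal(size=(h, 1)),
            W_linear=rng.normal(size=(d, d)), b_linear=rng.normal(size=d),
        )

    def test_equal_scores_give_uniform_weights(self, rng):
        E = rng.normal(size=(5, 4))
        p = self._params(rng)
        # identical embeddings for all views -> identical scores -> 1/4 each
        fr = attention_fuse({"s": E, "f": E, "m": E, "c": E}, **p)
        np.testing.assert_allclose(fr.omega, 0.25, rtol=1e-12)
        np.testing.assert_allclose(fr.E_fusion, E, rtol=1e-12)

    def test_dominant_view_limit(self):
        n, d = 3, 4
        # score is a direct readout of the first coordinate
        W1 = np.zeros((d, 2)); W1[0, 0] = 1.0
        b1 = np.zeros(2)
        W2 = np.array([[30.0], [0.0]])
        views = {
            "s": np.ones((n, d)),
            "f": -np.ones((n, d)),
            "m": -np.ones((n, d)),
            "c": -np.ones((n, d)),
        }
        fr = attention_fuse(views, W1, b1, W2, np.eye(d), np.zeros(d))
        assert np.all(fr.omega[:, 0] > 0.999)
        np.testing.assert_allclose(fr.E_fusion, views["s"], atol=1e-4)

    def test_matches_scalar_loop_oracle(self, rng):
        n, d, h = 6, 4, 3
        views = {v: rng.normal(size=(n, d)) for v in ("s", "f", "m", "c")}
        p = self._params(rng, d, h)
        fr = attention_fuse(views, **p)
        np.testing.assert_allclose(fr.omega.sum(axis=1), 1.0, rtol=1e-6)
        for i in range(n):
            raw = []
            for v in ("s", "f", "m", "c"):
                hid = np.tanh(p["W1"].T @ views[v][i] + p["b1"])
                raw.append((p["W2"].T @ hid).item())
            w = np.exp(raw - np.max(raw))
            w /= w.sum()
            np.testing.assert_allclose(fr.omega[i], w, rtol=1e-6)
            fused = sum(w[k] * views[v][i] for k, v in enumerate(("s", "f", "m", "c")))
            expected = p["W_linear"].T @ fused + p["b_linear"]
            np.testing.assert_allclose(fr.E_final[i], expected, rtol=1e-6)

    def test_requires_two_views(self, rng):
        p = self._params(rng)
        with pytest.raises(ValueError):
            attention_fuse({"s": np.ones((3, 4))}, **p)


class TestNBDecoder:
    def _zero_params(self, d=4, dh=3, g=5):
        return {
            "W_h": np.zeros((d, dh)), "b_h": np.zeros(dh),
            "bn_gamma": np.ones(dh), "bn_beta": np.zeros(dh),
            "W_mu": np.zeros((dh, g)), "b_mu": np.zeros(g),
            "W_theta": np.zeros((dh, g)), "b_theta": np.zeros(g),
        }

    def test_zero_input_zero_weights_constant_output(self):
        out = nb_decode(np.zeros((6, 4)), self._zero_params())
        expected = np.log(2.0) + 1e-4  # softplus(0) + epsilon
        np.testing.assert_allclose(out.mu, expected, rtol=1e-12)
        np.testing.assert_allclose(out.theta, expected, rtol=1e-12)

    def test_outputs_strictly_positive_for_random_inputs(self, rng):
        p = {k: rng.normal(size=v.shape) for k, v in self._zero_params().items()}
        p["bn_gamma"] = np.abs(p["bn_gamma"]) + 0.1
        out = nb_decode(rng.normal(size=(20, 4)) * 10, p)
        assert np.all(out.mu > 0) and np.all(out.theta > 0)
        assert out.mu.shape == (20, 5)


class TestNBLoglik:
    def test_closed_form_small_integers(self):
        # NB(mu=1, theta=1) is geometric(1/2): P(0)=1/2, P(1)=1/4
        assert nb_neg_loglik(np.array([[0.0]]), np.array([[1.0]]),
                             np.array([[1.0]])) == pytest.approx(np.log(2), abs=1e-9)
        assert nb_neg_loglik(np.array([[1.0]]), np.array([[1.0]]),
                             np.array([[1.0]])) == pytest.approx(np.log(4), abs=1e-9)

    def test_matches_scipy_pmf_on_integers(self, rng):
        X = rng.integers(0, 20, size=(4, 5)).astype(float)
        mu = rng.uniform(0.5, 8, size=(4, 5))
        theta = rng.uniform(0.5, 5, size=(4, 5))
        # scipy parameterization: n=theta, p=theta/(theta+mu)
        ll = nbinom.logpmf(X, theta, theta / (theta + mu))
        np.testing.assert_allclose(
            nb_neg_loglik(X, mu, theta), -ll.mean(), rtol=1e-10
        )

    def test_poisson_limit(self, rng):
        X = rng.integers(0, 15, size=(6, 6)).astype(float)
        mu = rng.uniform(0.5, 10, size=(6, 6))
        theta = np.full_like(mu, 1e6)
        np.testing.assert_allclose(
            nb_neg_loglik(X, mu, theta),
            -poisson.logpmf(X, mu).mean(),
            atol=1e-3,
        )

    def test_gamma_formula_direct_evaluation(self, rng):
        x, mu, th = 3.0, 2.5, 1.7
        direct = -(
            gammaln(x + th) - gammaln(x + 1) - gammaln(th)
            + th * np.log(th / (th + mu)) + x * np.log(mu / (mu + th))
        )
        assert nb_neg_loglik(np.array([[x]]), np.array([[mu]]),
                             np.array([[th]])) == pytest.approx(direct, rel=1e-12)

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            nb_neg_loglik(np.array([1.0]), np.array([0.0]), np.array([1.0]))


class TestConsistencyLoss:
    def test_identical_embeddings_zero(self, rng):
        E = rng.normal(size=(5, 3))
        assert consistency_loss([E, E.copy(), E.copy()]) == pytest.approx(0.0)

    def test_row_scale_invariance_in_similarity_mode(self, rng):
        E = rng.normal(size=(6, 4))
        assert consistency_loss([E, 2.0 * E, 0.5 * E]) == pytest.approx(0.0, abs=1e-9)

    def test_matches_double_loop_oracle(self, rng):
        Es = [rng.normal(size=(4, 2)) for _ in range(3)]
        normed = [E / np.sqrt((E * E).sum(1, keepdims=True) + 1e-8) for E in Es]
        Ks = [E @ E.T for E in normed]
        oracle = 0.0
        for a in range(3):
            for b in range(a + 1, 3):
                for i in range(4):
                    for j in range(4):
                        oracle += (Ks[a][i, j] - Ks[b][i, j]) ** 2
        oracle /= 16
        assert consistency_loss(Es) == pytest.approx(oracle, abs=1e-6)

    def test_embedding_space_mode_oracle(self, rng):
        Es = [rng.normal(size=(4, 2)) for _ in range(3)]
        normed = [E / np.sqrt((E * E).sum(1, keepdims=True) + 1e-8) for E in Es]
        oracle = sum(
            np.sum((normed[a] - normed[b]) ** 2)
            for a in range(3) for b in range(a + 1, 3)
        ) / 8
        assert consistency_loss(Es, mode="embedding_space") == pytest.approx(
            oracle, abs=1e-9
        )


class TestRegularizationLoss:
    def test_identical_rows_closed_form(self):
        E = np.tile([1.0, 2.0], (4, 1))
        P = np.ones((4, 4)) - np.eye(4)
        Q = np.zeros((4, 4))
        l_m, l_s, l_reg = regularization_loss(E, {"spatial": (P, Q)})
        # all cosine similarities are 1: each pair contributes -log sigma(1)
        sp1 = np.log1p(np.exp(-1.0))
        assert l_s == pytest.approx(sp1, rel=1e-5)
        assert l_reg == l_s and l_m == 0.0

    def test_empty_masks_zero(self, rng):
        E = rng.normal(size=(5, 3))
        zeros = (np.zeros((5, 5)), np.zeros((5, 5)))
        assert regularization_loss(E, {"spatial": zeros}) == (0.0, 0.0, 0.0)

    def test_full_complement_matches_double_loop_oracle(self, rng):
        n = 6
        E = rng.normal(size=(n, 3))
        coords = rng.uniform(0, 4, size=(n, 2))
        b = build_graph_bundle(E + 2, coords, None, r=2.5, k_expr=2)
        masks = sample_negative_masks(b.neighbor_sets, n, rng, mode="full")
        _, l_s, _ = regularization_loss(E, masks)
        En = E / np.linalg.norm(E, axis=1, keepdims=True)
        mat = En @ En.T

        def sigma(x):
            return 1.0 / (1.0 + np.exp(-x))

        total, count = 0.0, 0
        nbrs = b.neighbor_sets["spatial"]
        for i in range(n):
            for j in nbrs[i]:
                total += -np.log(sigma(mat[i, j])); count += 1
            for k in range(n):
                if k != i and k not in nbrs[i]:
                    total += -np.log(1 - sigma(mat[i, k])); count += 1
        assert l_s == pytest.approx(total / count, rel=1e-5)

    def test_sampled_negatives_match_positive_counts(self, rng):
        n = 12
        coords = rng.uniform(0, 6, size=(n, 2))
        b = build_graph_bundle(rng.uniform(0.1, 1, size=(n, 4)), coords, None,
                               r=2.5, k_expr=3)
        masks = sample_negative_masks(b.neighbor_sets, n, rng, mode="sampled")
        P, Q = masks["spatial"]
        # one negative per positive, capped by the available non-neighbors
        np.testing.assert_array_equal(
            Q.sum(axis=1), np.minimum(P.sum(axis=1), n - 1 - P.sum(axis=1))
        )
        assert np.all((P * Q) == 0)  # negatives disjoint from positives
        assert np.all(np.diag(Q) == 0)


class TestTotalLoss:
    def test_printed_weights_arithmetic(self):
        assert total_loss(1.0, 1.0, 1.0) == pytest.approx(11.1)

    def test_reduces_to_nb_when_beta_gamma_zero(self):
        assert total_loss(3.7, 9.9, 4.2, alpha=1.0, beta=0.0, gamma=0.0) == 3.7

    def test_linearity(self):
        assert total_loss(2.0, 2.0, 2.0) == pytest.approx(2 * total_loss(1, 1, 1))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            total_loss(1.0, 1.0, 1.0, alpha=-1.0)


class TestFullModel:
    def test_permutation_equivariance_of_final_embedding(self, rng):
        n, g = 15, 8
        X = rng.uniform(0.1, 5, size=(n, g))
        coords = rng.uniform(0, 8, size=(n, 2))
        M = rng.normal(size=(n, 5))
        cfg = ModelConfig(hidden_dim=6, latent_dim=4, attn_hidden=3,
                          decoder_hidden=5)
        b = build_graph_bundle(X, coords, M, r=3.0, k_expr=4, k_morph=4)
        model = STESHModel(g, cfg, np.random.default_rng(0), has_morphology=True)
        _, fusion, _ = model.forward(X, b)

        perm = rng.permutation(n)
        bp = build_graph_bundle(X[perm], coords[perm], M[perm],
                                r=3.0, k_expr=4, k_morph=4)
        model2 = STESHModel(g, cfg, np.random.default_rng(0), has_morphology=True)
        _, fusion_p, _ = model2.forward(X[perm], bp)
        np.testing.assert_allclose(
            fusion_p.E_final.data, fusion.E_final.data[perm], rtol=1e-5, atol=1e-8
        )

    def test_loss_gradients_match_finite_differences(self, rng):
        """End-to-end gradient check of the full training objective."""
        from tests.test_autodiff import numeric_grad

        n, g = 7, 5
        X = rng.uniform(0.5, 3, size=(n, g))
        coords = rng.uniform(0, 4, size=(n, 2))
        M = rng.normal(size=(n, 4))
        b = build_graph_bundle(X, coords, M, r=2.0, k_expr=2, k_morph=2)
        cfg = ModelConfig(hidden_dim=4, latent_dim=3, attn_hidden=2,
                          decoder_hidden=3)
        model = STESHModel(g, cfg, np.random.default_rng(1), has_morphology=True)
        masks = sample_negative_masks(b.neighbor_sets, n,
                                      np.random.default_rng(2), mode="full")

        def objective():
            emb, fusion, dec = model.forward(X, b)
            l_tot, _ = model.loss(X, emb, fusion, dec, masks)
            return l_tot

        l_tot = objective()
        l_tot.backward()
        for p in [model.W_s[0], model.W_c[1], model.attn["W1"],
                  model.attn["W_linear"], model.decoder["W_mu"],
                  model.decoder["bn_gamma"]]:
            analytic = p.grad.copy()

            def f(arr, p=p):
                old = p.data.copy()
                p.data = arr
                val = float(objective().data)
                p.data = old
                return val

            numeric = numeric_grad(f, p.data.copy(), eps=1e-5)
            np.testing.assert_allclose(analytic, numeric, rtol=2e-4, atol=1e-6)
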