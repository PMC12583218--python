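"""Encoder correctness: per-node aggregation oracle, attention behavior,
permutation equivariance, reconstruction loss."""

import numpy as np
import pytest

from heterodti import encoder as enc
from heterodti.autodiff import Tensor
from heterodti.graph import assemble_unified


def random_graph(rng, m, n):
    A_DD = (rng.random((m, m)) > 0.5).astype(float)
    A_DD = np.triu(A_DD, 1)
    A_DD = A_DD + A_DD.T
    A_TT = (rng.random((n, n)) > 0.5).astype(float)
    A_TT = np.triu(A_TT, 1)
    A_TT = A_TT + A_TT.T
    A_DT = (rng.random((m, n)) > 0.5).astype(float)
    return assemble_unified(A_DD, A_TT, A_DT)


def conv_oracle(Z_D, Z_T, graph, params, layer):
    """Independent per-node aggregation loop (attention off)."""
    lw = {k: v.data for k, v in params.layers[layer].items()}
    m, n = graph.m, graph.n
    h = params.h
    out_D = np.zeros((m, h))
    for i in range(m):
        acc = lw["B_D"][0].copy()
        for j in range(m):
            acc = acc + graph.N_DD[i, j] * (Z_D[j] @ lw["W_DD"])
        for j in range(n):
            acc = acc + graph.N_DT[i, j] * (Z_T[j] @ lw["W_DT"])
        out_D[i] = np.maximum(acc, 0.0)
    out_T = np.zeros((n, h))
    for i in range(n):
        acc = lw["B_T"][0].copy()
        for j in range(n):
            acc = acc + graph.N_TT[i, j] * (Z_T[j] @ lw["W_TT"])
        for j in range(m):
            acc = acc + graph.N_TD[i, j] * (Z_D[j] @ lw["W_TD"])
        out_T[i] = np.maximum(acc, 0.0)
    return out_D, out_T


class TestConvLayer:
    def test_matches_per_node_loop_oracle_on_many_random_graphs(self):
        """Vectorized block message passing equals independent nested-loop
        aggregation on 100 random graphs of at most 8 nodes."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            m = int(rng.integers(1, 5))
            n = int(rng.integers(1, 4))
            h = int(rng.integers(2, 6))
            graph = random_graph(rng, m, n)
            params = enc.init_encoder_params(3, 3, h, 1, rng)
            Z_D = rng.normal(size=(m, h))
            Z_T = rng.normal(size=(n, h))
            got_D, got_T = enc.conv_layer(Z_D, Z_T, graph, params, 0,
                                          use_attention=False)
            exp_D, exp_T = conv_oracle(Z_D, Z_T, graph, params, 0)
            worst = max(worst,
                        np.abs(got_D.data - exp_D).max(),
                        np.abs(got_T.data - exp_T).max())
        assert worst <= 1e-6

    def test_isolated_node_keeps_only_bias(self, rng):
        graph = assemble_unified(np.zeros((1, 1)), np.zeros((2, 2)),
                                 np.zeros((1, 2)))
        params = enc.init_encoder_params(3, 3, 4, 1, rng)
        params.layers[0]["B_D"].data[:] = np.array([1.0, -1.0, 2.0, 0.0])
        Z_D, Z_T = enc.conv_layer(rng.normal(size=(1, 4)),
                                  rng.normal(size=(2, 4)), graph, params, 0,
                                  use_attention=False)
        np.testing.assert_allclose(Z_D.data[0], [1.0, 0.0, 2.0, 0.0])

    def test_constant_attention_equals_attention_off_after_renorm(self, rng):
        """alpha identically c cancels under support renormalization."""
        graph = random_graph(rng, 4, 3)
        params = enc.init_encoder_params(3, 3, 5, 1, rng)
        # zero the attention MLPs -> sigmoid(0) = 0.5 on every edge
        for mlp in params.attention.values():
            for p in mlp.parameters():
                p.data[...] = 0.0
        Z_D = rng.normal(size=(4, 5))
        Z_T = rng.normal(size=(3, 5))
        on_D, on_T = enc.conv_layer(Z_D, Z_T, graph, params, 0,
                                    use_attention=True, renormalize=True)
        off_D, off_T = enc.conv_layer(Z_D, Z_T, graph, params, 0,
                                      use_attention=False)
        np.testing.assert_allclose(on_D.data, off_D.data, atol=1e-10)
        np.testing.assert_allclose(on_T.data, off_T.data, atol=1e-10)

    def test_shape_mismatch_raises(self, rng):
        graph = random_graph(rng, 3, 3)
        params = enc.init_encoder_params(3, 3, 4, 1, rng)
        with pytest.raises(ValueError):
            enc.conv_layer(rng.normal(size=(2, 4)), rng.normal(size=(3, 4)),
                           graph, params, 0)


class TestAttention:
    def test_zero_mlp_gives_half_on_support_only(self, rng):
        graph = random_graph(rng, 4, 3)
        params = enc.init_encoder_params(3, 3, 4, 1, rng)
        for mlp in params.attention.values():
            for p in mlp.parameters():
                p.data[...] = 0.0
        alpha = enc.attention_scores(rng.normal(size=(4, 4)),
                                     rng.normal(size=(3, 4)), graph, params,
                                     "DD")
        support = graph.support("DD")
        assert np.all(alpha[support] == 0.5)
        assert np.all(alpha[~support] == 0.0)

    def test_permuting_nodes_permutes_attention(self, rng):
        graph = random_graph(rng, 5, 3)
        params = enc.init_encoder_params(3, 3, 4, 1, rng)
        Z_D = rng.normal(size=(5, 4))
        Z_T = rng.normal(size=(3, 4))
        alpha = enc.attention_scores(Z_D, Z_T, graph, params, "DD")
        perm = rng.permutation(5)
        graph_p = assemble_unified(graph.A_DD[np.ix_(perm, perm)],
                                   graph.A_TT, graph.A_DT[perm])
        alpha_p = enc.attention_scores(Z_D[perm], Z_T, graph_p, params, "DD")
        np.testing.assert_allclose(alpha_p, alpha[np.ix_(perm, perm)],
                                   atol=1e-12)


class TestEncode:
    def test_single_layer_is_conv_on_projected_features(self, rng):
        graph = random_graph(rng, 3, 2)
        params = enc.init_encoder_params(6, 5, 4, 1, rng)
        X_D = rng.normal(size=(3, 6))
        X_T = rng.normal(size=(2, 5))
        Z_D, Z_T = enc.encode(X_D, X_T, graph, params, use_attention=False)
        P_D = X_D @ params.W_in_D.data + params.b_in_D.data
        P_T = X_T @ params.W_in_T.data + params.b_in_T.data
        E_D, E_T = enc.conv_layer(P_D, P_T, graph, params, 0,
                                  use_attention=False)
        np.testing.assert_allclose(Z_D.data, E_D.data)
        np.testing.assert_allclose(Z_T.data, E_T.data)

    def test_output_shapes(self, rng):
        graph = random_graph(rng, 4, 3)
        params = enc.init_encoder_params(6, 5, 7, 2, rng)
        Z_D, Z_T = enc.encode(rng.normal(size=(4, 6)),
                              rng.normal(size=(3, 5)), graph, params)
        assert Z_D.shape == (4, 7) and Z_T.shape == (3, 7)

    def test_identical_twin_drugs_get_identical_embeddings(self, rng):
        """Structurally identical nodes coincide (attention off)."""
        A_DD = np.zeros((3, 3))
        A_TT = np.zeros((2, 2))
        A_DT = np.array([[1.0, 0], [1.0, 0], [0, 1.0]])  # drugs 0,1 twins
        graph = assemble_unified(A_DD, A_TT, A_DT)
        params = enc.init_encoder_params(4, 4, 5, 1, rng)
        X_D = rng.normal(size=(3, 4))
        X_D[1] = X_D[0]
        X_T = rng.normal(size=(2, 4))
        Z_D, _ = enc.encode(X_D, X_T, graph, params, use_attention=False)
        np.testing.assert_allclose(Z_D.data[0], Z_D.data[1], atol=1e-12)

    def test_permutation_equivariance_full_encoder(self, rng):
        graph = random_graph(rng, 5, 4)
        params = enc.init_encoder_params(3, 3, 4, 2, rng)
        X_D = rng.normal(size=(5, 3))
        X_T = rng.normal(size=(4, 3))
        Z_D, Z_T = enc.encode(X_D, X_T, graph, params)
        perm = rng.permutation(5)
        graph_p = assemble_unified(graph.A_DD[np.ix_(perm, perm)],
                                   graph.A_TT, graph.A_DT[perm])
        Z_Dp, Z_Tp = enc.encode(X_D[perm], X_T, graph_p, params)
        np.testing.assert_allclose(Z_Dp.data, Z_D.data[perm], atol=1e-10)
        np.testing.assert_allclose(Z_Tp.data, Z_T.data, atol=1e-10)


class TestReconstruction:
    def test_zero_decoder_output_gives_sum_of_squares(self, rng):
        params = enc.init_encoder_params(4, 3, 5, 1, rng)
        for dec in (params.decoder_D, params.decoder_T):
            for p in dec.parameters():
                p.data[...] = 0.0
        X_D = rng.normal(size=(3, 4))
        X_T = rng.normal(size=(2, 3))
        loss = enc.reconstruction_loss(Tensor(rng.normal(size=(3, 5))),
                                       Tensor(rng.normal(size=(2, 5))),
                                       X_D, X_T, params)
        assert float(loss.data) == pytest.approx((X_D**2).sum()
                                                 + (X_T**2).sum())

    def test_loss_decreases_under_optimization(self, rng):
        """50 optimization steps shrink the reconstruction error on a small
        fixture."""
        from heterodti.autodiff import Adam

        params = enc.init_encoder_params(6, 6, 4, 1, rng)
        X_D = rng.normal(size=(6, 6))
        X_T = rng.normal(size=(4, 6))
        Z_D = Tensor(rng.normal(size=(6, 4)), requires_grad=True)
        Z_T = Tensor(rng.normal(size=(4, 4)), requires_grad=True)
        opt = Adam(params.parameters() + [Z_D, Z_T], lr=0.01)
        first = None
        for step in range(50):
            opt.zero_grad()
            loss = enc.reconstruction_loss(Z_D, Z_T, X_D, X_T, params)
            if step == 0:
                first = float(loss.data)
            loss.backward()
            opt.step()
        assert float(loss.data) < first


def test_checkpoint_round_trip(tmp_path, rng):
    """Saving and reloading parameters reproduces the encoder output."""
    graph = random_graph(rng, 4, 3)
    params = enc.init_encoder_params(5, 6, 4, 2, rng)
    X_D = rng.normal(size=(4, 5))
    X_T = rng.normal(size=(3, 6))
    before = enc.encode(X_D, X_T, graph, params)
    enc.save_checkpoint(params, tmp_path / "ckpt", drug_ids=["a", "b"],
                        extras={"relation_is_a": rng.normal(size=4)})
    loaded, manifest = enc.load_checkpoint(tmp_path / "ckpt")
    assert manifest["h"] == 4 and manifest["L"] == 2
    assert manifest["drug_ids"] == ["a", "b"]
    after = enc.encode(X_D, X_T, graph, loaded)
    np.testing.assert_array_equal(before[0].data, after[0].data)
    np.testing.assert_array_equal(before[1].data, after[1].data)
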