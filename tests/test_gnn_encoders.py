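"""Encoder families versus independent per-node aggregation oracles."""

import numpy as np
import pytest
import scipy.sparse as sp

from spatialgdl import (EncoderSpec, REGISTRY, cheb_forward, gatv2_forward,
                        gcn_forward, make_encoder, normalize_adjacency,
                        sage_forward, sgc_forward, tag_forward)
from spatialgdl.spatial_graph import SpatialGraph
from conftest import random_graph


def graph_from_adj(A, self_loops=True):
    A = sp.csr_matrix(A, dtype=float)
    n = A.shape[0]
    target = (A + sp.eye(n, format="csr")) if self_loops else A
    return SpatialGraph(A=A, A_norm=normalize_adjacency(A, self_loops),
                        degree=np.asarray(target.sum(axis=1)).ravel().astype(int),
                        params={"mode": "manual", "self_loops": self_loops})


# --------------------------------------------------------------- per-node oracles


def agg_oracle(M, X):
    """Row i of M X computed one node at a time."""
    M, X = np.asarray(M), np.asarray(X)
    out = np.zeros((M.shape[0], X.shape[1]))
    for i in range(M.shape[0]):
        for j in range(M.shape[1]):
            if M[i, j] != 0:
                out[i] += M[i, j] * X[j]
    return out


def oracle_gcn(X, An, Ws):
    h = X
    for li, W in enumerate(Ws):
        h = agg_oracle(An, h) @ W
        if li < len(Ws) - 1:
            h = np.maximum(h, 0)
    return h


def oracle_sgc(X, An, W, K):
    h = X
    for _ in range(K):
        h = agg_oracle(An, h)
    return h @ W


def oracle_tag(X, An, Ws, K):
    h, out = X, X @ Ws[0]
    for k in range(1, K + 1):
        h = agg_oracle(An, h)
        out = out + h @ Ws[k]
    return out


def oracle_cheb(X, An, Ws, K):
    lhat = -np.asarray(An)  # 2L/lambda_max - I with lambda_max=2, L=I-An
    terms = [X]
    if K >= 1:
        terms.append(agg_oracle(lhat, X))
    for k in range(2, K + 1):
        terms.append(2 * agg_oracle(lhat, terms[-1]) - terms[-2])
    return sum(t @ W for t, W in zip(terms, Ws))


def oracle_sage(X, A, W_self, W_neigh):
    A = np.asarray(A)
    out = np.zeros((X.shape[0], W_self.shape[1]))
    for i in range(X.shape[0]):
        nb = np.nonzero(A[i])[0]
        mean = X[nb].mean(axis=0) if len(nb) else np.zeros(X.shape[1])
        out[i] = X[i] @ W_self + mean @ W_neigh
    return out


def oracle_gatv2(X, A, W_src, W_dst, att, heads, out_dim):
    A = np.asarray(A) + np.eye(len(X))  # self loop in every neighborhood
    xs = (X @ W_src).reshape(len(X), heads, out_dim)
    xd = (X @ W_dst).reshape(len(X), heads, out_dim)
    out = np.zeros((len(X), heads, out_dim))
    for i in range(len(X)):
        nb = np.nonzero(A[i])[0]
        for h in range(heads):
            logits = []
            for j in nb:
                pre = xd[i, h] + xs[j, h]
                act = np.where(pre > 0, pre, 0.2 * pre)
                logits.append(float(att[h] @ act))
            logits = np.array(logits)
            alpha = np.exp(logits - logits.max())
            alpha /= alpha.sum()
            for a, j in zip(alpha, nb):
                out[i, h] += a * xs[j, h]
    return out.reshape(len(X), heads * out_dim)


# --------------------------------------------------------------- oracle equivalence


FAMS = sorted(REGISTRY)


@pytest.mark.parametrize("family", FAMS)
def test_matrix_form_equals_per_node_oracle(family):
    rng = np.random.default_rng(42)
    for trial in range(10):
        n = int(rng.integers(5, 31))
        A = random_graph(rng, n)
        g = graph_from_adj(A)
        An = g.A_norm.toarray()
        X = rng.normal(size=(n, 4))
        if family == "gcn":
            Ws = [rng.normal(size=(4, 6)), rng.normal(size=(6, 3))]
            got = gcn_forward(X, g.A_norm, Ws, activation="relu").data
            want = oracle_gcn(X, An, Ws)
        elif family == "sgc":
            W = rng.normal(size=(4, 3))
            got = sgc_forward(X, g.A_norm, W, K=2).data
            want = oracle_sgc(X, An, W, 2)
        elif family == "tag":
            Ws = [rng.normal(size=(4, 3)) for _ in range(3)]
            got = tag_forward(X, g.A_norm, Ws, K=2).data
            want = oracle_tag(X, An, Ws, 2)
        elif family == "chebyshev":
            Ws = [rng.normal(size=(4, 3)) for _ in range(4)]
            got = cheb_forward(X, g.A_norm, Ws, K=3).data
            want = oracle_cheb(X, An, Ws, 3)
        elif family == "sage":
            Ws, Wn = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
            got = sage_forward(X, g.neighbor_mean_operator(), Ws, Wn).data
            want = oracle_sage(X, A.toarray(), Ws, Wn)
        else:  # gatv2
            heads, dim = 2, 3
            Wsr = rng.normal(size=(4, heads * dim))
            Wds = rng.normal(size=(4, heads * dim))
            att = rng.normal(size=(heads, dim))
            coo = (g.A + sp.eye(n, format="csr")).tocoo()
            edges = np.column_stack([coo.row, coo.col])
            got = gatv2_forward(X, edges, n, Wsr, Wds, att, heads, dim).data
            want = oracle_gatv2(X, A.toarray(), Wsr, Wds, att, heads, dim)
        assert np.max(np.abs(got - want)) < 1e-5, f"{family} trial {trial}"


# --------------------------------------------------------------- closed forms


def test_gcn_single_node_self_loop_is_relu():
    g = graph_from_adj(sp.csr_matrix((1, 1)), self_loops=True)  # A_norm = I
    X = np.array([[-2.0, 3.0]])
    out = gcn_forward(X, g.A_norm, [np.eye(2), np.eye(2)], activation="relu").data
    np.testing.assert_allclose(out, [[0.0, 3.0]])


def test_gcn_two_cycle_swaps_rows():
    A = sp.csr_matrix(np.array([[0, 1], [1, 0]], dtype=float))
    g = graph_from_adj(A, self_loops=False)  # A_norm is the swap permutation
    X = np.eye(2)
    out = gcn_forward(X, g.A_norm, [np.eye(2)]).data  # single linear layer
    np.testing.assert_allclose(out, X[::-1])


def test_sgc_reductions():
    rng = np.random.default_rng(0)
    A = random_graph(rng, 8)
    g = graph_from_adj(A)
    X, W = rng.normal(size=(8, 4)), rng.normal(size=(4, 3))
    # K=1 equals a single linear graph convolution
    np.testing.assert_allclose(sgc_forward(X, g.A_norm, W, 1).data,
                               gcn_forward(X, g.A_norm, [W]).data, atol=1e-12)
    # edgeless graph with self loops: A_norm = I, so output = X W for any K
    g0 = graph_from_adj(sp.csr_matrix((8, 8)), self_loops=True)
    for K in (1, 2, 5):
        np.testing.assert_allclose(sgc_forward(X, g0.A_norm, W, K).data,
                                   X @ W, atol=1e-12)


def test_tag_degenerate_forms():
    rng = np.random.default_rng(1)
    g = graph_from_adj(random_graph(rng, 6))
    X, W0 = rng.normal(size=(6, 4)), rng.normal(size=(4, 3))
    np.testing.assert_allclose(tag_forward(X, g.A_norm, [W0], K=0).data,
                               X @ W0, atol=1e-12)
    # zero weights on hops >= 1 reduce to the plain linear map
    Ws = [W0, np.zeros((4, 3)), np.zeros((4, 3))]
    np.testing.assert_allclose(tag_forward(X, g.A_norm, Ws, K=2).data,
                               X @ W0, atol=1e-12)


def test_cheb_closed_forms():
    rng = np.random.default_rng(2)
    X, W0 = rng.normal(size=(5, 3)), rng.normal(size=(3, 2))
    g = graph_from_adj(random_graph(rng, 5))
    np.testing.assert_allclose(cheb_forward(X, g.A_norm, [W0], K=0).data,
                               X @ W0, atol=1e-12)
    # edgeless + self loops: L_hat = -I, so T_k = (-1)^k X
    g0 = graph_from_adj(sp.csr_matrix((5, 5)), self_loops=True)
    Ws = [np.eye(3), np.eye(3), np.eye(3)]
    want = X - X + X  # sum_k (-1)^k X for k = 0..2
    np.testing.assert_allclose(cheb_forward(X, g0.A_norm, Ws, K=2).data,
                               want, atol=1e-12)


def test_sage_isolated_and_identical_neighbors():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(3, 4))
    X[1] = X[2]  # node 0's neighbors (1, 2) are identical
    A = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
    Ws, Wn = rng.normal(size=(4, 2)), rng.normal(size=(4, 2))
    # isolated node: drop node 0's edges
    iso = np.zeros_like(A)
    g_iso = graph_from_adj(sp.csr_matrix(iso))
    out = sage_forward(X, g_iso.neighbor_mean_operator(), Ws, Wn).data
    np.testing.assert_allclose(out, X @ Ws, atol=1e-12)
    g = graph_from_adj(sp.csr_matrix(A))
    out = sage_forward(X, g.neighbor_mean_operator(), Ws, Wn).data
    np.testing.assert_allclose(out[0], X[0] @ Ws + X[1] @ Wn, atol=1e-12)


def test_gatv2_singleton_softmax_and_uniform_attention():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(1, 3))
    W = rng.normal(size=(3, 2))
    att = rng.normal(size=(1, 2))
    edges = np.array([[0, 0]])
    out = gatv2_forward(X, edges, 1, W, W.copy(), att, 1, 2).data
    np.testing.assert_allclose(out, X @ W, atol=1e-12)  # alpha = 1
    # identical neighbor features -> equal logits -> uniform 1/|N(i)| weights
    Xs = np.tile(rng.normal(size=(1, 3)), (4, 1))
    A = np.ones((4, 4)) - np.eye(4)
    coo = sp.coo_matrix(A + np.eye(4))
    edges = np.column_stack([coo.row, coo.col])
    out = gatv2_forward(Xs, edges, 4, W, W.copy(), att, 1, 2).data
    np.testing.assert_allclose(out, Xs @ W, atol=1e-10)


# --------------------------------------------------------------- registry / properties


def test_make_encoder_seeded_and_registry_errors():
    spec = EncoderSpec(family="gcn", in_dim=4, hidden_dim=8, out_dim=2)
    e1, e2 = make_encoder(spec, seed=5), make_encoder(spec, seed=5)
    for p, q in zip(e1.params, e2.params):
        np.testing.assert_array_equal(p.data, q.data)
    assert e1.W[0].shape == (4, 8) and e1.W[1].shape == (8, 2)
    with pytest.raises(KeyError, match="gatv2"):
        make_encoder(EncoderSpec(family="unimp", in_dim=4), seed=0)
    with pytest.raises(ValueError):
        EncoderSpec(family="gcn", in_dim=0)


@pytest.mark.parametrize("family", FAMS)
def test_permutation_equivariance(family):
    rng = np.random.default_rng(6)
    n = 12
    A = random_graph(rng, n)
    X = rng.normal(size=(n, 5))
    spec = EncoderSpec(family=family, in_dim=5, hidden_dim=7, out_dim=3,
                       heads=2, activation="relu")
    enc = make_encoder(spec, seed=9)
    out = enc.forward(X, graph_from_adj(A)).data
    perm = rng.permutation(n)
    P = np.eye(n)[perm]
    A_perm = sp.csr_matrix(P @ A.toarray() @ P.T)
    out_perm = enc.forward(X[perm], graph_from_adj(A_perm)).data
    np.testing.assert_allclose(out_perm, out[perm], atol=1e-8)


@pytest.mark.parametrize("family", ["gcn", "sgc", "tag", "chebyshev", "sage"])
def test_zero_input_zero_output_linear_families(family):
    rng = np.random.default_rng(7)
    g = graph_from_adj(random_graph(rng, 9))
    spec = EncoderSpec(family=family, in_dim=4, hidden_dim=6, out_dim=2,
                       activation="relu")
    enc = make_encoder(spec, seed=1)
    out = enc.forward(np.zeros((9, 4)), g).data
    np.testing.assert_allclose(out, 0.0, atol=1e-12)
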