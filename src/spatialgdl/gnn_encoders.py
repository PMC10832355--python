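"""Registry of GNN encoder families, each built from its message-passing rule.

Six families are implemented: GCN, SGC, TAG, Chebyshev, (mean-aggregator)
SAGE and GATv2. Every family satisfies the same forward contract —
``encoder.forward(X, graph) -> n x out_dim`` — so either graph deep-learning
module can use any of them as its encoder E. Parameters are Glorot-uniform
initialized from a seed and trained with the autodiff tape in
:mod:`._autodiff`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
import scipy.sparse as sp

from ._autodiff import Tensor, concat, segment_softmax, segment_sum, spmm
from .spatial_graph import SpatialGraph

LEAKY_SLOPE = 0.2  # GAT-style attention slope


@dataclass
class EncoderSpec:
    family: str
    in_dim: int
    hidden_dim: int = 128
    out_dim: int = 32
    hops_K: int = 2      # propagation depth for sgc / tag / chebyshev
    heads: int = 1       # attention heads for gatv2
    activation: str = "prelu"

    def __post_init__(self):
        for name in ("in_dim", "hidden_dim", "out_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hops_K < 1:
            raise ValueError("hops_K must be >= 1")
        if self.heads < 1:
            raise ValueError("heads must be >= 1")
        if self.activation not in ("relu", "prelu"):
            raise ValueError("activation must be 'relu' or 'prelu'")


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape=None) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape or (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


# ------------------------------------------------------------------ functional forms


def gcn_forward(X, a_norm, W_layers, activation=None, prelu_alphas=None) -> Tensor:
    """Stacked graph convolutions H <- act(A_norm H W); final layer linear."""
    h = _t(X)
    for li, W in enumerate(W_layers):
        h = spmm(a_norm, h) @ _t(W)
        if li < len(W_layers) - 1:
            h = _apply_act(h, activation, prelu_alphas, li)
    return h


def sgc_forward(X, a_norm, W, K: int) -> Tensor:
    """Simplified graph convolution: A_norm^K X W, no nonlinearity."""
    if K < 1:
        raise ValueError("K must be >= 1")
    h = _t(X)
    for _ in range(K):
        h = spmm(a_norm, h)
    return h @ _t(W)


def tag_forward(X, a_norm, W_hops, K: int = None) -> Tensor:
    """Topology-adaptive layer: sum_{k=0..K} A_norm^k X W_k."""
    X = _t(X)
    if K is None:
        K = len(W_hops) - 1
    if len(W_hops) != K + 1:
        raise ValueError(f"need K+1={K + 1} weight matrices, got {len(W_hops)}")
    h = X
    out = h @ _t(W_hops[0])
    for k in range(1, K + 1):
        h = spmm(a_norm, h)
        out = out + h @ _t(W_hops[k])
    return out


def cheb_forward(X, a_norm, W_hops, K: int = None) -> Tensor:
    """Chebyshev polynomial filter on the scaled Laplacian.

    With lambda_max fixed at 2 the scaled Laplacian reduces to
    L_hat = 2(I - A_norm)/2 - I = -A_norm; the recurrence is
    T_0 = X, T_1 = L_hat X, T_k = 2 L_hat T_{k-1} - T_{k-2}.
    """
    X = _t(X)
    if K is None:
        K = len(W_hops) - 1
    if len(W_hops) != K + 1:
        raise ValueError(f"need K+1={K + 1} weight matrices, got {len(W_hops)}")
    neg = sp.csr_matrix(-sp.csr_matrix(a_norm, dtype=float))
    out = X @ _t(W_hops[0])
    if K == 0:
        return out
    t_prev, t_cur = X, spmm(neg, X)
    out = out + t_cur @ _t(W_hops[1])
    for k in range(2, K + 1):
        t_next = 2.0 * spmm(neg, t_cur) - t_prev
        out = out + t_next @ _t(W_hops[k])
        t_prev, t_cur = t_cur, t_next
    return out


def sage_forward(X, mean_op, W_self, W_neigh) -> Tensor:
    """Mean-aggregator SAGE layer (pre-activation):
    W_self x_i + W_neigh mean_{j in N(i)} x_j; isolated nodes use a zero mean."""
    X = _t(X)
    return X @ _t(W_self) + spmm(mean_op, X) @ _t(W_neigh)


def gatv2_forward(X, edges, n: int, W_src, W_dst, att, heads: int,
                  out_dim: int) -> Tensor:
    """GATv2 attention layer.

    Per directed edge (j -> i): e_ij = a^T LeakyReLU(W_l x_i + W_r x_j),
    alpha = softmax over the in-neighborhood of i (self loop included in
    `edges`), output h_i = sum_j alpha_ij (W_r x_j), heads concatenated.
    """
    X = _t(X)
    src, dst = edges[:, 0], edges[:, 1]
    m = len(src)
    xs = (X @ _t(W_src)).reshape(n, heads, out_dim)   # source (message) half
    xd = (X @ _t(W_dst)).reshape(n, heads, out_dim)   # destination half
    pair = xd.gather_rows(dst) + xs.gather_rows(src)
    scores = (pair.leaky_relu(LEAKY_SLOPE) * _t(att)).sum(axis=2)  # (m, heads)
    alpha = segment_softmax(scores, dst, n)
    msgs = alpha.reshape(m, heads, 1) * xs.gather_rows(src)
    agg = segment_sum(msgs, dst, n)                    # (n, heads, out_dim)
    return agg.reshape(n, heads * out_dim)


def _apply_act(h: Tensor, activation, prelu_alphas, layer_idx: int) -> Tensor:
    if activation is None or activation == "linear":
        return h
    if activation == "relu":
        return h.relu()
    if activation == "prelu":
        alpha = prelu_alphas[layer_idx]
        r = h.relu()
        return r + alpha * (h - r)
    raise ValueError(f"unknown activation {activation!r}")


# ------------------------------------------------------------------ encoder classes


class Encoder:
    """Base class: holds an EncoderSpec and a flat parameter list."""

    def __init__(self, spec: EncoderSpec, seed: int):
        self.spec = spec
        self.params: List[Tensor] = []
        rng = np.random.default_rng(seed)
        self.prelu_alphas: List[Tensor] = []
        if spec.activation == "prelu":
            for _ in range(self.n_activations()):
                a = Tensor(np.array(0.25), requires_grad=True)
                self.prelu_alphas.append(a)
        self._init_params(rng)
        self.params.extend(self.prelu_alphas)

    def n_activations(self) -> int:
        return 1  # one hidden activation for two-layer stacks

    def _init_params(self, rng):
        raise NotImplementedError

    def forward(self, X, graph: SpatialGraph) -> Tensor:
        raise NotImplementedError

    def __call__(self, X, graph):
        return self.forward(X, graph)


class GCNEncoder(Encoder):
    def _init_params(self, rng):
        s = self.spec
        self.W = [_glorot(rng, s.in_dim, s.hidden_dim),
                  _glorot(rng, s.hidden_dim, s.out_dim)]
        self.params.extend(self.W)

    def forward(self, X, graph):
        return gcn_forward(X, graph.A_norm, self.W, self.spec.activation,
                           self.prelu_alphas)


class SGCEncoder(Encoder):
    def n_activations(self):
        return 0  # linear model

    def _init_params(self, rng):
        s = self.spec
        self.W = _glorot(rng, s.in_dim, s.out_dim)
        self.params.append(self.W)

    def forward(self, X, graph):
        return sgc_forward(X, graph.A_norm, self.W, self.spec.hops_K)


class _HopStackEncoder(Encoder):
    """Two stacked multi-hop layers (TAG / Chebyshev) with one activation."""

    hop_fn = None

    def _init_params(self, rng):
        s = self.spec
        self.W1 = [_glorot(rng, s.in_dim, s.hidden_dim) for _ in range(s.hops_K + 1)]
        self.W2 = [_glorot(rng, s.hidden_dim, s.out_dim) for _ in range(s.hops_K + 1)]
        self.params.extend(self.W1 + self.W2)

    def forward(self, X, graph):
        fn = type(self).hop_fn
        h = fn(X, graph.A_norm, self.W1, self.spec.hops_K)
        h = _apply_act(h, self.spec.activation, self.prelu_alphas, 0)
        return fn(h, graph.A_norm, self.W2, self.spec.hops_K)


class TAGEncoder(_HopStackEncoder):
    hop_fn = staticmethod(tag_forward)


class ChebEncoder(_HopStackEncoder):
    hop_fn = staticmethod(cheb_forward)


class SAGEEncoder(Encoder):
    def _init_params(self, rng):
        s = self.spec
        self.W = [(_glorot(rng, s.in_dim, s.hidden_dim),
                   _glorot(rng, s.in_dim, s.hidden_dim)),
                  (_glorot(rng, s.hidden_dim, s.out_dim),
                   _glorot(rng, s.hidden_dim, s.out_dim))]
        for ws, wn in self.W:
            self.params.extend([ws, wn])

    def forward(self, X, graph):
        mean_op = graph.neighbor_mean_operator()
        h = sage_forward(X, mean_op, *self.W[0])
        h = _apply_act(h, self.spec.activation, self.prelu_alphas, 0)
        return sage_forward(h, mean_op, *self.W[1])


class GATv2Encoder(Encoder):
    def _init_params(self, rng):
        s = self.spec
        h = s.heads
        self.l1 = (_glorot(rng, s.in_dim, h * s.hidden_dim),
                   _glorot(rng, s.in_dim, h * s.hidden_dim),
                   _glorot(rng, s.hidden_dim, 1, shape=(h, s.hidden_dim)))
        self.l2 = (_glorot(rng, h * s.hidden_dim, s.out_dim),
                   _glorot(rng, h * s.hidden_dim, s.out_dim),
                   _glorot(rng, s.out_dim, 1, shape=(1, s.out_dim)))
        for layer in (self.l1, self.l2):
            self.params.extend(layer)

    def forward(self, X, graph):
        n = graph.n_spots
        # attention neighborhoods always include the self loop
        coo = (graph.A + sp.eye(n, format="csr")).tocoo()
        edges = np.column_stack([coo.row, coo.col])
        s = self.spec
        h = gatv2_forward(X, edges, n, self.l1[0], self.l1[1], self.l1[2],
                          s.heads, s.hidden_dim)
        h = _apply_act(h, s.activation, self.prelu_alphas, 0)
        return gatv2_forward(h, edges, n, self.l2[0], self.l2[1], self.l2[2],
                             1, s.out_dim)


class GraphLayer:
    """One pre-activation message-passing layer of a registry family.

    Used where a module needs a single layer rather than a full stacked
    encoder (e.g. the first layer of the variational autoencoder). Output
    width is ``out_dim`` (``heads * out_dim`` for gatv2 with concatenation).
    """

    def __init__(self, family: str, in_dim: int, out_dim: int,
                 rng: np.random.Generator, hops_K: int = 2, heads: int = 1):
        if family not in REGISTRY:
            raise KeyError(
                f"unknown encoder family {family!r}; available: {sorted(REGISTRY)}")
        self.family = family
        self.hops_K = hops_K
        self.heads = heads
        self.out_dim = out_dim
        self.params: List[Tensor] = []
        if family in ("gcn", "sgc"):
            self.W = _glorot(rng, in_dim, out_dim)
            self.params.append(self.W)
        elif family in ("tag", "chebyshev"):
            self.W = [_glorot(rng, in_dim, out_dim) for _ in range(hops_K + 1)]
            self.params.extend(self.W)
        elif family == "sage":
            self.W = (_glorot(rng, in_dim, out_dim), _glorot(rng, in_dim, out_dim))
            self.params.extend(self.W)
        elif family == "gatv2":
            self.W = (_glorot(rng, in_dim, heads * out_dim),
                      _glorot(rng, in_dim, heads * out_dim),
                      _glorot(rng, out_dim, 1, shape=(heads, out_dim)))
            self.params.extend(self.W)

    @property
    def width(self) -> int:
        return self.heads * self.out_dim if self.family == "gatv2" else self.out_dim

    def forward(self, X, graph: SpatialGraph) -> Tensor:
        f = self.family
        if f == "gcn":
            return spmm(graph.A_norm, _t(X)) @ self.W
        if f == "sgc":
            return sgc_forward(X, graph.A_norm, self.W, self.hops_K)
        if f == "tag":
            return tag_forward(X, graph.A_norm, self.W, self.hops_K)
        if f == "chebyshev":
            return cheb_forward(X, graph.A_norm, self.W, self.hops_K)
        if f == "sage":
            return sage_forward(X, graph.neighbor_mean_operator(), *self.W)
        # gatv2
        n = graph.n_spots
        coo = (graph.A + sp.eye(n, format="csr")).tocoo()
        edges = np.column_stack([coo.row, coo.col])
        return gatv2_forward(X, edges, n, self.W[0], self.W[1], self.W[2],
                             self.heads, self.out_dim)


REGISTRY = {
    "gcn": GCNEncoder,
    "sgc": SGCEncoder,
    "tag": TAGEncoder,
    "chebyshev": ChebEncoder,
    "sage": SAGEEncoder,
    "gatv2": GATv2Encoder,
}


def make_encoder(spec: EncoderSpec, seed: int = 0) -> Encoder:
    """Instantiate a seeded encoder; unknown families raise a registry error."""
    if spec.family not in REGISTRY:
        raise KeyError(
            f"unknown encoder family {spec.family!r}; available: "
            f"{sorted(REGISTRY)}")
    return REGISTRY[spec.family](spec, seed)
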