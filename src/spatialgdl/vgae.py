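"""Variational graph autoencoder (VGAE) module.

A first GNN layer maps features to a hidden representation X_tilde; a
propagation head produces the Gaussian posterior parameters mu and
log sigma^2 (sharing one weight matrix W1 by default, so the two heads are
numerically identical; a separate-heads variant is available behind a
flag). Latents are sampled by the reparameterization trick Z = mu +
sigma * eps, the adjacency is reconstructed through the inner-product
decoder sigmoid(Z Z^T), and training minimizes class-weighted
reconstruction BCE plus the KL divergence from the standard-normal prior.
The clustering embedding is the posterior mean mu.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from ._autodiff import Adam, Tensor, spmm
from .gnn_encoders import EncoderSpec, GraphLayer, _glorot
from .io_core import EmbeddingMatrix
from .preprocessing import FeatureMatrix
from .spatial_graph import SpatialGraph

log = logging.getLogger(__name__)

DEFAULT_EPOCHS = 400
DEFAULT_LR = 1e-2
_CLAMP = 1e-12


@dataclass
class VgaeState:
    encoder_first: object
    head_weight: object          # W1 (shared) or (W1_mu, W1_sigma)
    mu: np.ndarray = None
    log_sigma2: np.ndarray = None
    train_log: List[dict] = field(default_factory=list)
    seed: int = 0
    share_heads: bool = True


# ------------------------------------------------------------------ pure operations


def vgae_encode(X, a_norm, W0, W1, share_heads: bool = True, W1_sigma=None,
                activation: str = "relu"):
    """Two-layer GCN-style encoding to posterior (mu, log sigma^2).

    X_tilde = ReLU(A_norm X W0); mu = A_norm X_tilde W1. With shared heads
    (the default) log sigma^2 uses the same W1 and equals mu element-wise;
    otherwise it uses W1_sigma.
    """
    X = X if isinstance(X, Tensor) else Tensor(np.asarray(X, dtype=float))
    W0 = W0 if isinstance(W0, Tensor) else Tensor(W0)
    W1 = W1 if isinstance(W1, Tensor) else Tensor(W1)
    xt = spmm(a_norm, X) @ W0
    xt = xt.relu() if activation == "relu" else xt
    prop = spmm(a_norm, xt)
    mu = prop @ W1
    if share_heads:
        log_sigma2 = prop @ W1
    else:
        if W1_sigma is None:
            raise ValueError("separate heads require W1_sigma")
        W1_sigma = W1_sigma if isinstance(W1_sigma, Tensor) else Tensor(W1_sigma)
        log_sigma2 = prop @ W1_sigma
    return mu, log_sigma2


def reparameterize(mu, log_sigma2, seed: int = None, epsilon=None):
    """Z = mu + exp(log sigma^2 / 2) * eps, eps ~ N(0, 1)."""
    mu_t = mu if isinstance(mu, Tensor) else Tensor(np.asarray(mu, dtype=float))
    ls_t = log_sigma2 if isinstance(log_sigma2, Tensor) else \
        Tensor(np.asarray(log_sigma2, dtype=float))
    if epsilon is None:
        if seed is None:
            raise ValueError("provide either seed or epsilon")
        epsilon = np.random.default_rng(seed).standard_normal(mu_t.data.shape)
    eps = Tensor(np.asarray(epsilon, dtype=float))
    return mu_t + (0.5 * ls_t).exp() * eps


def decode_inner_product(Z):
    """Edge probabilities P = sigmoid(Z Z^T); symmetric, entries in (0,1)."""
    Z = Z if isinstance(Z, Tensor) else Tensor(np.asarray(Z, dtype=float))
    return (Z @ Z.T).sigmoid()


def gaussian_kl(mu, log_sigma2) -> float:
    """(1/n) sum_i sum_a 0.5 (exp(log s2) + mu^2 - 1 - log s2); >= 0."""
    mu = np.asarray(mu, dtype=float)
    ls = np.asarray(log_sigma2, dtype=float)
    n = mu.shape[0]
    return float(0.5 * np.sum(np.exp(ls) + mu ** 2 - 1.0 - ls) / n)


def vgae_loss(P, A_target, mu, log_sigma2, pos_weight: float = None,
              kl_scale: float = 1.0) -> Tuple[float, float, float]:
    """(total, recon, kl) of the negative evidence lower bound.

    recon is the positive-class-weighted binary cross-entropy between the
    decoded probabilities P and the binary target (self loops counted as
    positives); pos_weight defaults to (n^2 - nnz)/nnz. kl is the mean per
    spot of the Gaussian KL to the standard-normal prior.
    """
    P = P.data if isinstance(P, Tensor) else np.asarray(P, dtype=float)
    A = A_target.toarray() if sp.issparse(A_target) else np.asarray(A_target, dtype=float)
    n = A.shape[0]
    npos = A.sum()
    if pos_weight is None:
        # degenerate all-edge / no-edge targets fall back to a plain mean
        pos_weight = (n * n - npos) / npos if 0 < npos < n * n else 1.0
    Pc = np.clip(P, _CLAMP, 1 - _CLAMP)
    per = -(pos_weight * A * np.log(Pc) + (1.0 - A) * np.log(1.0 - Pc))
    # normalize so unit weights give a plain mean
    recon = float(per.sum() / (pos_weight * npos + (n * n - npos)))
    kl = gaussian_kl(mu.data if isinstance(mu, Tensor) else mu,
                     log_sigma2.data if isinstance(log_sigma2, Tensor) else log_sigma2)
    return recon + kl_scale * kl, recon, kl


# ------------------------------------------------------------------ training


class _VgaeNet:
    """One family-specific first layer + shared/separate propagation heads."""

    def __init__(self, spec: EncoderSpec, share_heads: bool, seed: int):
        rng = np.random.default_rng(seed)
        self.first = GraphLayer(spec.family, spec.in_dim, spec.hidden_dim,
                                rng, hops_K=spec.hops_K, heads=spec.heads)
        width = self.first.width
        self.W1 = _glorot(rng, width, spec.out_dim)
        self.W1_sigma = None if share_heads else _glorot(rng, width, spec.out_dim)
        self.share_heads = share_heads
        self.params = self.first.params + [self.W1] + \
            ([] if share_heads else [self.W1_sigma])

    def encode(self, X, graph: SpatialGraph):
        xt = self.first.forward(X, graph).relu()
        prop = spmm(graph.A_norm, xt)
        mu = prop @ self.W1
        log_sigma2 = prop @ self.W1 if self.share_heads else prop @ self.W1_sigma
        return mu, log_sigma2


def train_vgae(fm: FeatureMatrix, graph: SpatialGraph, spec: EncoderSpec,
               epochs: int = DEFAULT_EPOCHS, lr: float = DEFAULT_LR,
               seed: int = 0, share_heads: bool = True,
               kl_scale: float = 1.0, spot_ids: Optional[list] = None):
    """Train the VGAE objective; returns (EmbeddingMatrix, VgaeState).

    The reconstruction target is A + I (self loops as positives). One
    reparameterization sample per epoch; the final embedding is the
    posterior mean mu, making downstream clustering deterministic.
    """
    net = _VgaeNet(spec, share_heads, seed)
    opt = Adam(net.params, lr=lr)
    X = np.asarray(fm.X, dtype=float)
    n = X.shape[0]
    A_target = ((graph.A + sp.eye(n, format="csr")) > 0).astype(float).toarray()
    npos = A_target.sum()
    pos_weight = (n * n - npos) / npos if 0 < npos < n * n else 1.0
    denom = pos_weight * npos + (n * n - npos)
    weight = np.where(A_target > 0, pos_weight, 1.0)
    eps_rng = np.random.default_rng(seed + 2)
    state = VgaeState(encoder_first=net.first,
                      head_weight=net.W1 if share_heads else (net.W1, net.W1_sigma),
                      seed=seed, share_heads=share_heads)

    for epoch in range(epochs):
        opt.zero_grad()
        mu, log_sigma2 = net.encode(X, graph)
        Z = reparameterize(mu, log_sigma2,
                           epsilon=eps_rng.standard_normal(mu.data.shape))
        logits = Z @ Z.T
        # weighted BCE-with-logits: w * (softplus(x) - y*x), stable
        per = Tensor(weight) * (logits.softplus() - Tensor(A_target) * logits)
        recon = per.sum() * (1.0 / denom)
        kl = ((0.5 / n) *
              (log_sigma2.exp() + mu.square() - 1.0 - log_sigma2).sum())
        loss = recon + kl_scale * kl
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite VGAE loss at epoch {epoch}")
        loss.backward()
        opt.step()
        state.train_log.append({"total": float(loss.data),
                                "recon": float(recon.data),
                                "kl": float(kl.data)})

    mu, log_sigma2 = net.encode(X, graph)
    state.mu = mu.data
    state.log_sigma2 = log_sigma2.data
    if spot_ids is None:
        spot_ids = [f"spot_{i}" for i in range(n)]
    emb = EmbeddingMatrix(values=mu.data, spot_ids=spot_ids,
                          module_tag="vgae", encoder_tag=spec.family)
    return emb, state
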