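"""Deep graph infomax (DGI) module.

Trains an encoder unsupervised by contrasting node embeddings of the real
graph (positive samples) against embeddings of a corrupted graph in which
feature rows are permuted but the topology is kept (negative samples). A
readout pools node embeddings into a global summary S; a bilinear
discriminator scores how likely an embedding belongs with S; the objective
is a standard binary cross-entropy over positive/negative scores. After
training, the positive-branch embeddings are the latent representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from ._autodiff import Adam, Tensor
from .gnn_encoders import Encoder, EncoderSpec, make_encoder
from .io_core import EmbeddingMatrix
from .preprocessing import FeatureMatrix
from .spatial_graph import SpatialGraph

log = logging.getLogger(__name__)

DEFAULT_EPOCHS = 500
DEFAULT_LR = 1e-3
_CLAMP = 1e-12


@dataclass
class DgiState:
    encoder: Encoder
    discriminator_weight: Tensor  # d x d bilinear form
    train_log: List[float] = field(default_factory=list)
    seed: int = 0


def corrupt(X: np.ndarray, A, seed: int):
    """Negative-sample corruption: permute feature rows, keep the topology.

    Returns (X_perm, A) — the adjacency object is reused unchanged.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(X.shape[0])
    return np.asarray(X)[perm], A


def readout(H) -> np.ndarray:
    """Global summary S = sigmoid(column means of H)."""
    H = H.data if isinstance(H, Tensor) else np.asarray(H, dtype=float)
    if H.shape[0] == 0:
        raise ValueError("readout of an empty embedding")
    m = H.mean(axis=0)
    return 1.0 / (1.0 + np.exp(-m))


def _readout_t(H: Tensor) -> Tensor:
    if H.data.shape[0] == 0:
        raise ValueError("readout of an empty embedding")
    return H.mean(axis=0).sigmoid()


def discriminate(h, S, W) -> float:
    """Bilinear discriminator D(h, S) = sigmoid(h^T W S)."""
    h = np.asarray(h, dtype=float)
    S = np.asarray(S, dtype=float)
    W = W.data if isinstance(W, Tensor) else np.asarray(W, dtype=float)
    return float(1.0 / (1.0 + np.exp(-(h @ W @ S))))


def dgi_loss(pos_scores, neg_scores) -> float:
    """BCE objective: -mean log D(h,S) - mean log(1 - D(h_bar,S)).

    Scores are clamped to [1e-12, 1-1e-12] before the log. At uninformative
    scores of 0.5 everywhere the loss is 2 ln 2.
    """
    p = np.clip(np.asarray(pos_scores, dtype=float), _CLAMP, 1 - _CLAMP)
    q = np.clip(np.asarray(neg_scores, dtype=float), _CLAMP, 1 - _CLAMP)
    return float(-np.mean(np.log(p)) - np.mean(np.log(1.0 - q)))


def _scores_t(H: Tensor, S: Tensor, W: Tensor) -> Tensor:
    return (H @ W) @ S.reshape(-1, 1)  # (n,1) logits


def train_dgi(fm: FeatureMatrix, graph: SpatialGraph, spec: EncoderSpec,
              epochs: int = DEFAULT_EPOCHS, lr: float = DEFAULT_LR,
              seed: int = 0, resample_corruption: bool = True,
              spot_ids: Optional[list] = None):
    """Train the DGI objective; returns (EmbeddingMatrix, DgiState).

    Each epoch draws a fresh feature-row permutation as the negative sample
    (set ``resample_corruption=False`` to corrupt once), scores both branches
    against the positive summary, and minimizes the BCE by Adam. Fully
    reproducible from ``seed``.
    """
    encoder = make_encoder(spec, seed=seed)
    rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31))
    d = spec.out_dim
    W_disc = Tensor(rng.uniform(-np.sqrt(3.0 / d), np.sqrt(3.0 / d), size=(d, d)),
                    requires_grad=True)
    params = encoder.params + [W_disc]
    opt = Adam(params, lr=lr)
    X = np.asarray(fm.X, dtype=float)
    state = DgiState(encoder=encoder, discriminator_weight=W_disc, seed=seed)

    corrupt_seed = int(np.random.default_rng(seed + 1).integers(2**31))
    Xn, _ = corrupt(X, graph.A, corrupt_seed)
    for epoch in range(epochs):
        if resample_corruption:
            Xn, _ = corrupt(X, graph.A, corrupt_seed + epoch)
        opt.zero_grad()
        H = encoder.forward(X, graph)
        Hn = encoder.forward(Xn, graph)
        S = _readout_t(H)
        pos_logits = _scores_t(H, S, W_disc)
        neg_logits = _scores_t(Hn, S, W_disc)
        # stable BCE on logits: -log sigmoid(x) = softplus(-x)
        loss = (-pos_logits).softplus().mean() + neg_logits.softplus().mean()
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite DGI loss at epoch {epoch}")
        loss.backward()
        opt.step()
        state.train_log.append(float(loss.data))

    H = encoder.forward(X, graph)
    if spot_ids is None:
        spot_ids = [f"spot_{i}" for i in range(X.shape[0])]
    emb = EmbeddingMatrix(values=H.data, spot_ids=spot_ids,
                          module_tag="dgi", encoder_tag=spec.family)
    return emb, state
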