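"""Spot-spot adjacency from spatial coordinates, plus symmetric normalization.

Two construction modes mirror standard neighbor models: k-nearest-neighbor
(symmetrized by union, so an edge exists if either endpoint selects the
other) and fixed-radius. The normalized operator is the degree-symmetric
form A_norm = D^(-1/2) (A + I?) D^(-1/2); self loops are added before
normalization when requested (the GCN convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors


@dataclass
class SpatialGraph:
    """Binary symmetric adjacency A and its symmetric normalization."""

    A: sp.csr_matrix            # binary, zero diagonal
    A_norm: sp.csr_matrix       # D^(-1/2) (A [+ I]) D^(-1/2)
    degree: np.ndarray          # row sums of the normalized target
    params: dict = field(default_factory=dict)

    @property
    def n_spots(self) -> int:
        return self.A.shape[0]

    def edges(self) -> np.ndarray:
        """Directed edge list (both orientations) of the *normalization target*
        (includes self loops when they were added), as an (m, 2) int array."""
        coo = self._norm_target().tocoo()
        return np.column_stack([coo.row, coo.col])

    def _norm_target(self) -> sp.csr_matrix:
        a = self.A
        if self.params.get("self_loops", True):
            a = (a + sp.eye(a.shape[0], format="csr")).tocsr()
        return a

    def neighbor_mean_operator(self) -> sp.csr_matrix:
        """Row-stochastic D^(-1) A over the raw adjacency (no self loops);
        isolated spots get an all-zero row. Used by mean aggregators."""
        d = np.asarray(self.A.sum(axis=1)).ravel()
        inv = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 0.0)
        return sp.diags(inv) @ self.A

    def export_edge_list(self, path: str) -> None:
        coo = sp.triu(self.A, k=1).tocoo()
        with open(path, "w") as fh:
            fh.write("i\tj\tweight\n")
            for i, j, w in zip(coo.row, coo.col, coo.data):
                fh.write(f"{i}\t{j}\t{w:g}\n")


def normalize_adjacency(A, self_loops: bool = True) -> sp.csr_matrix:
    """Degree-symmetric normalization D^(-1/2) (A + I*self_loops) D^(-1/2).

    Zero-degree rows map to zero rows. Raises on asymmetric input.
    """
    A = sp.csr_matrix(A, dtype=float)
    if (abs(A - A.T) > 1e-12).nnz:
        raise ValueError("adjacency must be symmetric")
    if A.nnz and A.data.min() < 0:
        raise ValueError("adjacency must be non-negative")
    if self_loops:
        A = (A + sp.eye(A.shape[0], format="csr")).tocsr()
    d = np.asarray(A.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        d_inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    Dm = sp.diags(d_inv_sqrt)
    return (Dm @ A @ Dm).tocsr()


def build_graph(coords, mode: str = "knn", k: int = 6, radius: float = None,
                self_loops: bool = True) -> SpatialGraph:
    """Construct the spatial neighbor graph from n x 2 coordinates.

    knn mode connects each spot to its k nearest Euclidean neighbors and
    symmetrizes by union; radius mode connects every pair at distance <=
    radius. Distance ties break by ascending spot index. An edgeless radius
    graph is allowed (with a warning), not an error.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spots to build a graph")
    if mode == "knn":
        if not 1 <= k < n:
            raise ValueError(f"knn mode requires 1 <= k < n_spots, got k={k}, n={n}")
        nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute").fit(coords)
        dist, idx = nn.kneighbors(coords)
        rows, cols = [], []
        for i in range(n):
            # drop self, keep k nearest; ties resolved by (distance, index)
            order = sorted((d, j) for d, j in zip(dist[i], idx[i]) if j != i)[:k]
            for _, j in order:
                rows.append(i)
                cols.append(j)
        A = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
        A = ((A + A.T) > 0).astype(float)  # union symmetrization
        params = {"mode": "knn", "k": k, "self_loops": self_loops}
    elif mode == "radius":
        if radius is None or radius <= 0:
            raise ValueError("radius mode requires a positive radius")
        nn = NearestNeighbors(radius=radius, algorithm="brute").fit(coords)
        graph = nn.radius_neighbors_graph(coords, mode="connectivity")
        A = sp.csr_matrix(graph, dtype=float)
        A.setdiag(0)
        A.eliminate_zeros()
        A = ((A + A.T) > 0).astype(float)
        if A.nnz == 0:
            warnings.warn(f"radius {radius} yields an edgeless graph")
        params = {"mode": "radius", "radius": radius, "self_loops": self_loops}
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'knn' or 'radius'")

    target = (A + sp.eye(n, format="csr")).tocsr() if self_loops else A
    degree = np.asarray(target.sum(axis=1)).ravel().astype(int)
    A_norm = normalize_adjacency(A, self_loops=self_loops)
    return SpatialGraph(A=A.tocsr(), A_norm=A_norm, degree=degree, params=params)
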