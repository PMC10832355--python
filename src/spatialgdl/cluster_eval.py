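"""Cluster latent embeddings, score against ground truth, rank combinations.

Clustering of the latent space uses a seeded full-covariance Gaussian
mixture when the number of domains is known, or Leiden community detection
on a kNN graph of the embeddings otherwise. Accuracy is the adjusted Rand
index (chance-corrected pair agreement); NMI is reported alongside but
never used for ranking. Encoder families are ranked per dataset by
descending ARI (mean rank on ties) and averaged across datasets; the
accuracy/efficiency trade-off set is the intersection of the most accurate
and fastest families.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, asdict, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.mixture import GaussianMixture

from .dgi import train_dgi
from .gnn_encoders import EncoderSpec
from .io_core import EmbeddingMatrix, SpatialDataset
from .preprocessing import build_feature_matrix
from .spatial_graph import build_graph
from .vgae import train_vgae


@dataclass
class BenchmarkRecord:
    module_tag: str
    encoder_tag: str
    ari: Optional[float]
    nmi: Optional[float]
    wall_time_s: float
    n_clusters_found: int
    seed: int
    status: str = "ok"


# ------------------------------------------------------------------ metrics


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions (permutation-invariant)."""
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label vectors differ in length: {len(labels_a)} vs {len(labels_b)}")
    return float(adjusted_rand_score(labels_a, labels_b))


def nmi(labels_a, labels_b) -> float:
    """Mutual information normalized by the arithmetic mean of entropies."""
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label vectors differ in length: {len(labels_a)} vs {len(labels_b)}")
    return float(normalized_mutual_info_score(labels_a, labels_b,
                                              average_method="arithmetic"))


# ------------------------------------------------------------------ clustering


def cluster_embeddings(emb, k: int = None, resolution: float = 1.0,
                       method: str = "gmm", seed: int = 0) -> np.ndarray:
    """Hard cluster labels for an embedding.

    gmm: Gaussian mixture, `k` full-covariance components, seeded
    initialization, assignment by max posterior. leiden: community
    detection at `resolution` on a k=15 nearest-neighbor graph of the
    embedding rows.
    """
    values = emb.values if isinstance(emb, EmbeddingMatrix) else np.asarray(emb)
    n = values.shape[0]
    if method == "gmm":
        if k is None or k < 1:
            raise ValueError("gmm clustering requires k >= 1")
        if k > n:
            raise ValueError(f"k={k} exceeds number of spots {n}")
        if k == 1:
            return np.zeros(n, dtype=int)
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             random_state=seed, n_init=1, max_iter=200,
                             reg_covar=1e-5)
        return gm.fit_predict(values)
    if method == "leiden":
        return _leiden(values, resolution, seed)
    raise ValueError(f"unknown clustering method {method!r}")


def _leiden(values: np.ndarray, resolution: float, seed: int) -> np.ndarray:
    import igraph
    import leidenalg
    from sklearn.neighbors import kneighbors_graph
    k = min(15, values.shape[0] - 1)
    adj = kneighbors_graph(values, n_neighbors=k, include_self=False)
    adj = ((adj + adj.T) > 0).tocoo()
    g = igraph.Graph(n=values.shape[0],
                     edges=[(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j])
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed)
    return np.asarray(part.membership, dtype=int)


# ------------------------------------------------------------------ ranking


def average_rank(records_by_dataset: Dict[str, Sequence[BenchmarkRecord]]) -> pd.DataFrame:
    """Average per-dataset ARI rank of each encoder (rank 1 = best ARI,
    ties share the mean rank). Every encoder must appear in every dataset."""
    encoders = None
    per_dataset = {}
    for ds_name, records in records_by_dataset.items():
        aris = {}
        for r in records:
            if r.ari is None:
                continue
            aris.setdefault(r.encoder_tag, []).append(r.ari)
        enc_set = sorted(aris)
        if encoders is None:
            encoders = enc_set
        else:
            missing = set(encoders) ^ set(enc_set)
            if missing:
                raise ValueError(
                    f"encoder(s) {sorted(missing)} missing from dataset {ds_name!r}")
        best = np.array([max(aris[e]) for e in encoders])
        per_dataset[ds_name] = rankdata(-best, method="average")
    table = pd.DataFrame(per_dataset, index=encoders)
    table["average_rank"] = table.mean(axis=1)
    return table.sort_values("average_rank")


def tradeoff_select(records: Sequence[BenchmarkRecord], top_n: int = 10) -> Dict[str, set]:
    """Per module: encoders in both the top_n by ARI and top_n by speed."""
    out = {}
    for module in sorted({r.module_tag for r in records}):
        rows = [r for r in records if r.module_tag == module and r.ari is not None]
        by_acc = sorted(rows, key=lambda r: -r.ari)[:top_n]
        by_speed = sorted(rows, key=lambda r: r.wall_time_s)[:top_n]
        out[module] = ({r.encoder_tag for r in by_acc} &
                       {r.encoder_tag for r in by_speed})
    return out


# ------------------------------------------------------------------ benchmark sweep


def run_benchmark(ds: SpatialDataset, modules: Sequence[str],
                  specs: Sequence[EncoderSpec], epochs: int = 200,
                  lr: float = None, seed: int = 0, n_hvg: int = 3000,
                  graph_mode: str = "knn", k_neighbors: int = 6,
                  radius: float = None,
                  cluster_method: str = "gmm") -> List[BenchmarkRecord]:
    """Sweep every module x encoder combination on one dataset.

    Preprocessing and graph construction are shared across combinations;
    wall time is measured around training only. A failing combination is
    recorded with status='failed' instead of aborting the sweep. Returns
    exactly len(modules) * len(specs) records.
    """
    fm = build_feature_matrix(ds, n_hvg=n_hvg)
    graph = build_graph(ds.coordinates, mode=graph_mode, k=k_neighbors,
                        radius=radius)
    n_domains = len(np.unique(ds.labels)) if ds.labels is not None else None
    records = []
    for module in modules:
        for spec in specs:
            spec = EncoderSpec(family=spec.family, in_dim=fm.X.shape[1],
                               hidden_dim=spec.hidden_dim, out_dim=spec.out_dim,
                               hops_K=spec.hops_K, heads=spec.heads,
                               activation=spec.activation)
            try:
                t0 = time.perf_counter()
                if module == "dgi":
                    emb, _ = train_dgi(fm, graph, spec, epochs=epochs,
                                       lr=lr or 1e-3, seed=seed,
                                       spot_ids=ds.spot_ids)
                elif module == "vgae":
                    emb, _ = train_vgae(fm, graph, spec, epochs=epochs,
                                        lr=lr or 1e-2, seed=seed,
                                        spot_ids=ds.spot_ids)
                else:
                    raise ValueError(f"unknown module {module!r}")
                wall = time.perf_counter() - t0
                if n_domains is not None:
                    pred = cluster_embeddings(emb, k=n_domains,
                                              method=cluster_method, seed=seed)
                    rec_ari = ari(ds.labels, pred)
                    rec_nmi = nmi(ds.labels, pred)
                else:
                    pred = cluster_embeddings(emb, method="leiden", seed=seed)
                    rec_ari = rec_nmi = None
                records.append(BenchmarkRecord(
                    module_tag=module, encoder_tag=spec.family,
                    ari=rec_ari, nmi=rec_nmi, wall_time_s=wall,
                    n_clusters_found=len(np.unique(pred)), seed=seed))
            except Exception:  # noqa: BLE001 - sweep must survive one failure
                records.append(BenchmarkRecord(
                    module_tag=module, encoder_tag=spec.family,
                    ari=None, nmi=None, wall_time_s=0.0,
                    n_clusters_found=0, seed=seed, status="failed"))
    return records


def records_to_frame(records: Sequence[BenchmarkRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])
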