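"""Central data containers and readers/writers for the formats the tool touches.

A :class:`SpatialDataset` bundles a spot-by-feature expression matrix with
2-D spatial coordinates, optional ground-truth domain labels, and names.
Supported on-disk layouts: a CSV/TSV triplet, a MatrixMarket (MTX) triplet,
and an AnnData ``.h5ad`` container with coordinates in ``obsm["spatial"]``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.io


Matrix = Union[np.ndarray, sp.spmatrix]

FORMATS = ("csv", "mtx", "h5ad")


class AlignmentError(ValueError):
    """Row counts of expression / coordinates / labels disagree."""


class ValidationError(ValueError):
    """Dataset content violates an invariant (negative counts, NaN coords...)."""


@dataclass
class SpatialDataset:
    """Expression + 2-D coordinates for one spatial omics sample.

    ``expression`` may be dense or scipy-sparse; it is kept as given and
    densified lazily downstream. Coordinates are (x, y) columns in the
    dataset's native length unit.
    """

    expression: Matrix
    coordinates: np.ndarray
    labels: Optional[np.ndarray] = None
    feature_names: Optional[Sequence[str]] = None
    spot_ids: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = self.expression.shape[0]
        if self.spot_ids is None:
            self.spot_ids = [f"spot_{i}" for i in range(n)]
        self.spot_ids = list(map(str, self.spot_ids))
        if self.feature_names is None:
            self.feature_names = [f"feature_{j}" for j in range(self.expression.shape[1])]
        self.feature_names = list(map(str, self.feature_names))
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
        self.validate()

    @property
    def n_spots(self) -> int:
        return self.expression.shape[0]

    @property
    def n_features(self) -> int:
        return self.expression.shape[1]

    def dense_expression(self) -> np.ndarray:
        x = self.expression
        return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x, dtype=float)

    def validate(self) -> None:
        n = self.expression.shape[0]
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValidationError(
                f"coordinates must be n x 2, got shape {self.coordinates.shape}")
        if self.coordinates.shape[0] != n:
            raise AlignmentError(
                f"expression has {n} rows but coordinates has "
                f"{self.coordinates.shape[0]} rows")
        if len(self.spot_ids) != n:
            raise AlignmentError(
                f"expression has {n} rows but spot_ids has {len(self.spot_ids)} entries")
        if len(self.feature_names) != self.expression.shape[1]:
            raise AlignmentError(
                f"expression has {self.expression.shape[1]} columns but "
                f"feature_names has {len(self.feature_names)} entries")
        if len(set(self.spot_ids)) != n:
            raise ValidationError("duplicated spot_ids")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError("coordinates contain non-finite values")
        xmin = self.expression.min() if sp.issparse(self.expression) \
            else np.min(self.expression) if self.expression.size else 0.0
        if xmin < 0:
            raise ValidationError(f"negative expression entries (min {xmin})")
        if self.labels is not None:
            if len(self.labels) != n:
                raise AlignmentError(
                    f"expression has {n} rows but labels has {len(self.labels)} entries")
            if len(np.unique(self.labels)) < 1:
                raise ValidationError("labels present but empty")


@dataclass
class EmbeddingMatrix:
    """Spot-by-latent-dimension matrix produced by a trained GDL module."""

    values: np.ndarray
    spot_ids: Sequence[str]
    module_tag: str = "dgi"
    encoder_tag: str = "gcn"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.spot_ids = list(map(str, self.spot_ids))
        if self.values.ndim != 2:
            raise ValidationError("embedding values must be 2-D")
        if len(self.spot_ids) != self.values.shape[0]:
            raise AlignmentError(
                f"embedding has {self.values.shape[0]} rows but "
                f"{len(self.spot_ids)} spot_ids")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValidationError("embedding contains non-finite values")


# --------------------------------------------------------------------------- read


def read_dataset(path: str, fmt: str = None) -> SpatialDataset:
    """Read a SpatialDataset from `path`.

    ``fmt`` is one of {"csv", "mtx", "h5ad"}; when None it is inferred
    (.h5ad file -> h5ad; directory containing matrix.mtx -> mtx; else csv).
    """
    if fmt is None:
        if str(path).endswith(".h5ad"):
            fmt = "h5ad"
        elif os.path.isdir(path) and os.path.exists(os.path.join(path, "matrix.mtx")):
            fmt = "mtx"
        else:
            fmt = "csv"
    if fmt not in FORMATS:
        raise ValueError(f"unknown format tag {fmt!r}; expected one of {FORMATS}")
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "mtx":
        return _read_mtx(path)
    return _read_h5ad(path)


def _read_coords_labels(path):
    coords = pd.read_csv(os.path.join(path, "coordinates.csv"), index_col=0)
    coordinates = coords[["x", "y"]].to_numpy(dtype=float)
    labels = None
    labels_path = os.path.join(path, "labels.csv")
    if os.path.exists(labels_path):
        labels = pd.read_csv(labels_path, index_col=0)["label"].to_numpy(dtype=int)
    return list(coords.index.astype(str)), coordinates, labels


def _read_csv(path: str) -> SpatialDataset:
    mat = pd.read_csv(os.path.join(path, "expression.csv"), index_col=0)
    spot_ids, coordinates, labels = _read_coords_labels(path)
    return SpatialDataset(
        expression=mat.to_numpy(dtype=float),
        coordinates=coordinates,
        labels=labels,
        feature_names=list(mat.columns.astype(str)),
        spot_ids=list(mat.index.astype(str)),
    )


def _read_mtx(path: str) -> SpatialDataset:
    # spots are MTX rows; barcodes.tsv = spot ids, features.tsv = feature names
    x = scipy.io.mmread(os.path.join(path, "matrix.mtx")).tocsr()
    barcodes = pd.read_csv(os.path.join(path, "barcodes.tsv"), header=None)[0]
    features = pd.read_csv(os.path.join(path, "features.tsv"), header=None)[0]
    spot_ids, coordinates, labels = _read_coords_labels(path)
    return SpatialDataset(
        expression=x,
        coordinates=coordinates,
        labels=labels,
        feature_names=list(features.astype(str)),
        spot_ids=list(barcodes.astype(str)),
    )


def _read_h5ad(path: str) -> SpatialDataset:
    import anndata
    adata = anndata.read_h5ad(path)
    if "spatial" not in adata.obsm:
        raise ValidationError("h5ad container has no obsm['spatial'] coordinates")
    labels = None
    if "label" in adata.obs:
        labels = adata.obs["label"].to_numpy(dtype=int)
    return SpatialDataset(
        expression=adata.X if sp.issparse(adata.X) else np.asarray(adata.X, dtype=float),
        coordinates=np.asarray(adata.obsm["spatial"], dtype=float),
        labels=labels,
        feature_names=list(adata.var_names.astype(str)),
        spot_ids=list(adata.obs_names.astype(str)),
    )


# --------------------------------------------------------------------------- write


def write_dataset(ds: SpatialDataset, path: str, fmt: str = "csv") -> None:
    """Write `ds` so that :func:`read_dataset` round-trips it within 1e-9."""
    if fmt not in FORMATS:
        raise ValueError(f"unknown format tag {fmt!r}; expected one of {FORMATS}")
    if fmt == "h5ad":
        _write_h5ad(ds, path)
        return
    os.makedirs(path, exist_ok=True)
    coords = pd.DataFrame(ds.coordinates, index=ds.spot_ids, columns=["x", "y"])
    coords.to_csv(os.path.join(path, "coordinates.csv"))
    if ds.labels is not None:
        pd.DataFrame({"label": ds.labels}, index=ds.spot_ids).to_csv(
            os.path.join(path, "labels.csv"))
    if fmt == "csv":
        pd.DataFrame(ds.dense_expression(), index=ds.spot_ids,
                     columns=ds.feature_names).to_csv(os.path.join(path, "expression.csv"))
    else:  # mtx
        scipy.io.mmwrite(os.path.join(path, "matrix.mtx"),
                         sp.coo_matrix(ds.expression))
        pd.Series(ds.spot_ids).to_csv(os.path.join(path, "barcodes.tsv"),
                                      index=False, header=False)
        pd.Series(ds.feature_names).to_csv(os.path.join(path, "features.tsv"),
                                           index=False, header=False)


def _write_h5ad(ds: SpatialDataset, path: str) -> None:
    import anndata
    adata = anndata.AnnData(
        X=ds.expression if sp.issparse(ds.expression)
        else np.asarray(ds.dense_expression()),
        obs=pd.DataFrame(index=pd.Index(ds.spot_ids, name="spot_id")),
        var=pd.DataFrame(index=pd.Index(ds.feature_names, name="feature")),
    )
    adata.obsm["spatial"] = np.asarray(ds.coordinates)
    if ds.labels is not None:
        adata.obs["label"] = np.asarray(ds.labels)
    adata.write_h5ad(path)


def write_embeddings(emb: EmbeddingMatrix, path: str) -> None:
    """Write an embedding as TSV: spot_id column + one column per latent dim.

    The header encodes module/encoder tags as ``<module>.<encoder>.<j>``
    column names, so a 4x2 embedding yields a 5-line file.
    """
    cols = [f"{emb.module_tag}.{emb.encoder_tag}.{j}"
            for j in range(emb.values.shape[1])]
    df = pd.DataFrame(emb.values, index=pd.Index(emb.spot_ids, name="spot_id"),
                      columns=cols)
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_embeddings(path: str) -> EmbeddingMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1]:
        module_tag, encoder_tag = df.columns[0].split(".")[:2]
    else:
        module_tag, encoder_tag = "dgi", "gcn"
    return EmbeddingMatrix(values=df.to_numpy(dtype=float),
                           spot_ids=list(df.index.astype(str)),
                           module_tag=module_tag, encoder_tag=encoder_tag)
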