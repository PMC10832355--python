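"""Feature-matrix construction: HVG selection, normalization, scaling.

Pipeline (deterministic): library-size normalize each spot to the median
total count, log1p, rank features by normalized dispersion (variance/mean of
the log-normalized values), keep the top ``n_hvg``, optionally z-score per
feature. Protein-scale panels (few features) skip HVG selection entirely.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io_core import SpatialDataset

log = logging.getLogger(__name__)

#: panels at or below this many features keep every feature (imaging panels)
SMALL_PANEL_SIZE = 50

DEFAULT_N_HVG = 3000


@dataclass
class FeatureMatrix:
    """Dense spot-by-HVG matrix ready for the GDL modules."""

    X: np.ndarray
    hvg_index: np.ndarray
    scaling_stats: dict = field(default_factory=dict)

    @property
    def n_spots(self) -> int:
        return self.X.shape[0]


def _log_normalized(expression) -> np.ndarray:
    """Library-size normalize to the median total, then log1p."""
    x = np.asarray(expression.todense()) if sp.issparse(expression) \
        else np.asarray(expression, dtype=float)
    totals = x.sum(axis=1)
    nonzero = totals > 0
    if not np.all(nonzero):
        warnings.warn(f"{np.sum(~nonzero)} spot(s) have zero total count; "
                      "their normalized rows are all zeros")
    target = np.median(totals[nonzero]) if nonzero.any() else 1.0
    scale = np.where(nonzero, target / np.where(nonzero, totals, 1.0), 0.0)
    return np.log1p(x * scale[:, None])


def select_hvgs(expression, n_top: int = DEFAULT_N_HVG) -> np.ndarray:
    """Indices of the `n_top` most variable features by normalized dispersion.

    Dispersion is variance/mean of the log-normalized matrix; features with
    zero mean get dispersion 0. Ties break by ascending column index. When
    ``n_top >= n_features`` every feature is kept in original order.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    n_features = expression.shape[1]
    if n_top >= n_features:
        return np.arange(n_features)
    ln = _log_normalized(expression)
    mean = ln.mean(axis=0)
    var = ln.var(axis=0)
    if not np.any(var > 0):
        raise ValueError("no variable features: expression matrix is constant")
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    # stable sort on -dispersion => ties keep ascending original index
    order = np.argsort(-dispersion, kind="stable")
    return order[:n_top]


def normalize_features(expression, hvg_index=None, standardize: bool = True) -> FeatureMatrix:
    """Build the feature matrix X for the selected features.

    Normalization removes sequencing depth (proportional count rows map to
    the same normalized row); the optional z-score guards constant features
    by clamping sd to 1, yielding zero columns.
    """
    ln = _log_normalized(expression)
    if hvg_index is None:
        hvg_index = np.arange(ln.shape[1])
    hvg_index = np.asarray(hvg_index, dtype=int)
    X = ln[:, hvg_index]
    stats = {}
    if standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd_guard = np.where(sd > 1e-12, sd, 1.0)
        X = (X - mean) / sd_guard
        stats = {"mean": mean, "sd": sd_guard}
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values after normalization")
    return FeatureMatrix(X=X, hvg_index=hvg_index, scaling_stats=stats)


def build_feature_matrix(ds: SpatialDataset, n_hvg: int = DEFAULT_N_HVG,
                         standardize: bool = True) -> FeatureMatrix:
    """End-to-end preprocessing of a dataset.

    Small panels (<= 50 features, e.g. imaging-based protein data) keep all
    features; otherwise the top ``n_hvg`` by dispersion are selected.
    """
    if ds.n_features <= SMALL_PANEL_SIZE or n_hvg >= ds.n_features:
        hvg = np.arange(ds.n_features)
    else:
        hvg = select_hvgs(ds.expression, n_hvg)
    return normalize_features(ds.expression, hvg, standardize=standardize)
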