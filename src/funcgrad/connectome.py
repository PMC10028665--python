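"""Functional connectivity matrices and the group-template construction.

Individual connectomes are Pearson correlation matrices over node time
series, optionally z-score normalised to mitigate site differences. The
group template averages the raw correlation matrices of all scans, applies
the Fisher z (atanh) transform off-diagonal, and is then sparsified by
keeping the top fraction of connections of each column — the operator the
gradient embedding decomposes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .conditioning import RoiTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "correlation_matrix",
    "zscore_matrix",
    "group_template_matrix",
    "threshold_top_fraction",
]

logger = logging.getLogger(__name__)

VALUE_STATES = ("pearson_r", "zscored", "fisher_z")
SPARSITY_STATES = ("dense", "column_thresholded")


@dataclass
class ConnectivityMatrix:
    """N x N node-pair association values with an explicit value state
    (``pearson_r``, ``zscored`` or ``fisher_z``) and sparsity state
    (``dense`` or ``column_thresholded``)."""

    values: np.ndarray
    state: str = "pearson_r"
    sparsity: str = "dense"
    node_ids: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity values must be a square matrix")
        if self.state not in VALUE_STATES:
            raise ValueError(f"unknown value state {self.state!r}")
        if self.sparsity not in SPARSITY_STATES:
            raise ValueError(f"unknown sparsity state {self.sparsity!r}")
        if self.node_ids is None:
            self.node_ids = [f"n{i + 1:04d}" for i in range(self.values.shape[0])]
        if len(self.node_ids) != self.values.shape[0]:
            raise ValueError("node_ids length does not match matrix size")
        if self.state == "pearson_r" and self.sparsity == "dense":
            v = self.values
            if not np.allclose(v, v.T, atol=1e-10):
                raise ValueError("a Pearson matrix must be symmetric")
            if np.any(v > 1 + 1e-10) or np.any(v < -1 - 1e-10):
                raise ValueError("Pearson correlations must lie in [-1, 1]")
            if not np.allclose(np.diag(v), 1.0, atol=1e-10):
                raise ValueError("a Pearson matrix must have unit diagonal")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def _offdiag_mask(self) -> np.ndarray:
        return ~np.eye(self.n_nodes, dtype=bool)


def correlation_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation matrix of the node time series.

    Requires at least 3 time points; nodes with zero temporal variance are
    rejected by name since their correlation is undefined.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points for a correlation matrix")
    sd = ts.data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.node_ids[i] for i in dead]
        raise ValueError(f"zero-variance nodes have no defined correlation: {names}")
    r = np.corrcoef(ts.data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=r, state="pearson_r", node_ids=list(ts.node_ids))


def zscore_matrix(cm: ConnectivityMatrix) -> ConnectivityMatrix:
    """Standardise the off-diagonal entries to mean 0, SD 1 within the matrix.

    The diagonal is excluded from the statistics and set to 0. The map is a
    monotone affine transform, so symmetry and the rank order of
    connections are preserved.
    """
    if cm.state != "pearson_r":
        raise ValueError(f"z-scoring expects a pearson_r matrix, got {cm.state!r}")
    mask = cm._offdiag_mask()
    off = cm.values[mask]
    mu = off.mean()
    sd = off.std()  # population SD: the matrix itself is the population
    if sd <= 1e-12 * max(1.0, abs(mu)):
        raise ValueError("off-diagonal entries are constant; z-score undefined")
    z = (cm.values - mu) / sd
    np.fill_diagonal(z, 0.0)
    return replace(cm, values=z, state="zscored", meta={**cm.meta, "zscore": True})


def group_template_matrix(matrices: Iterable[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Average raw correlation matrices over scans and Fisher z-transform.

    The entrywise mean of the Pearson matrices is computed first, then
    z = atanh(mean r) is applied off-diagonal (diagonal set to 0). A mean
    correlation of exactly +/-1 is clipped to +/-(1 - 1e-7) with a warning.
    """
    mats = list(matrices)
    if not mats:
        raise ValueError("need at least one scan to build a group template")
    n = mats[0].n_nodes
    for m in mats:
        if m.state != "pearson_r":
            raise ValueError("group template averages raw pearson_r matrices")
        if m.n_nodes != n:
            raise ValueError("all matrices must have the same size")
    mean_r = np.mean([m.values for m in mats], axis=0)
    mask = ~np.eye(n, dtype=bool)
    clip = 1.0 - 1e-7
    n_clipped = int(np.count_nonzero(np.abs(mean_r[mask]) >= 1.0))
    if n_clipped:
        logger.warning(
            "group template: %d off-diagonal mean correlations at |r| = 1 "
            "clipped to +/-%g before Fisher z",
            n_clipped,
            clip,
        )
    z = np.arctanh(np.clip(mean_r, -clip, clip))
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        values=z,
        state="fisher_z",
        node_ids=list(mats[0].node_ids),
        meta={"n_scans": len(mats)},
    )


def threshold_top_fraction(cm: ConnectivityMatrix, fraction: float = 0.1) -> ConnectivityMatrix:
    """Keep the top ``ceil(fraction * N)`` entries of each column, zero the rest.

    Columns are thresholded independently, so the result may be asymmetric.
    Ties that span the cutoff are all kept (and logged), so the retained
    count can exceed the nominal one only under exact ties.
    """
    if cm.sparsity != "dense":
        raise ValueError("matrix is already column-thresholded")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = cm.n_nodes
    k = math.ceil(fraction * n)
    values = cm.values
    out = np.zeros_like(values)
    tie_columns = []
    for j in range(n):
        col = values[:, j]
        cutoff = np.partition(col, n - k)[n - k]
        keep = col >= cutoff
        if keep.sum() > k:
            tie_columns.append(j)
        out[keep, j] = col[keep]
    if tie_columns:
        logger.info(
            "top-fraction threshold: ties at the cutoff in %d column(s); "
            "all tied values kept",
            len(tie_columns),
        )
    return replace(
        cm,
        values=out,
        sparsity="column_thresholded",
        meta={**cm.meta, "threshold_fraction": fraction, "retained_per_column": k},
    )
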