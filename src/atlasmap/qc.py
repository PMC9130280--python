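"""Cell-level quality control and depth normalization.

Cells are removed when they have fewer than ``min_genes`` detected genes or
when mitochondrial genes make up strictly more than ``max_mito_fraction`` of
their raw counts (defaults 200 and 8.5%). Surviving cells are depth-scaled
and log-transformed: ``value = ln(1 + count * scale_target / cell_total)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

__all__ = ["QCThresholds", "QCReport", "filter_cells", "normalize"]

REASON_LOW_GENES = "low_genes"
REASON_HIGH_MITO = "high_mito"


@dataclass(frozen=True)
class QCThresholds:
    """Cell filters: strict inequalities, so a cell at exactly the
    mito threshold is retained and one at exactly ``min_genes`` detected
    genes is retained."""

    min_genes: int = 200
    max_mito_fraction: float = 0.085
    scale_target: float = 10_000.0

    def __post_init__(self) -> None:
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")
        if self.scale_target <= 0:
            raise ValueError("scale_target must be positive")


@dataclass
class QCReport:
    per_cell: pd.DataFrame  # n_genes_detected, mito_fraction, passed, reason
    summary: dict

    def __post_init__(self) -> None:
        s = self.summary
        removed = s["removed_low_genes"] + s["removed_high_mito"] - s["removed_both"]
        if s["cells_out"] != s["cells_in"] - removed:
            raise ValueError("QC summary does not reconcile with removals")


def _mito_flags(adata: AnnData, mito_flags) -> np.ndarray:
    if mito_flags is None:
        if "mito" not in adata.var:
            raise ValueError("no mito flags given and adata.var has no 'mito' column")
        mito_flags = adata.var["mito"].to_numpy()
    flags = np.asarray(mito_flags, dtype=bool)
    if flags.shape != (adata.n_vars,):
        raise ValueError("mito flags must cover every gene exactly once")
    return flags


def filter_cells(adata: AnnData, thresholds: QCThresholds | None = None,
                 mito_flags=None) -> tuple[AnnData, QCReport]:
    """Remove low-complexity and high-mitochondrial cells.

    A cell is removed iff its detected-gene count is < ``min_genes`` OR its
    mitochondrial count fraction (computed on raw counts) is strictly >
    ``max_mito_fraction``. The gene set and cell order are unchanged.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty count matrix")
    thresholds = thresholds or QCThresholds()
    flags = _mito_flags(adata, mito_flags)

    X = adata.X
    if sparse.issparse(X):
        X = X.tocsr()
        detected = np.asarray((X > 0).sum(axis=1)).ravel()
        totals = np.asarray(X.sum(axis=1)).ravel()
        mito_counts = np.asarray(X[:, flags].sum(axis=1)).ravel()
    else:
        X = np.asarray(X)
        detected = (X > 0).sum(axis=1)
        totals = X.sum(axis=1)
        mito_counts = X[:, flags].sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    low_genes = detected < thresholds.min_genes
    high_mito = mito_fraction > thresholds.max_mito_fraction
    passed = ~(low_genes | high_mito)

    reasons = np.array([""] * adata.n_obs, dtype=object)
    for mask, tag in ((low_genes, REASON_LOW_GENES), (high_mito, REASON_HIGH_MITO)):
        reasons[mask] = np.where(reasons[mask] == "", tag, reasons[mask] + ";" + tag)

    per_cell = pd.DataFrame(
        {
            "n_genes_detected": detected,
            "mito_fraction": mito_fraction,
            "passed": passed,
            "reason": reasons,
        },
        index=adata.obs_names,
    )
    summary = {
        "cells_in": int(adata.n_obs),
        "cells_out": int(passed.sum()),
        "removed_low_genes": int(low_genes.sum()),
        "removed_high_mito": int(high_mito.sum()),
        "removed_both": int((low_genes & high_mito).sum()),
    }
    if summary["cells_out"] == 0:
        warnings.warn("QC removed every cell", stacklevel=2)
    return adata[passed].copy(), QCReport(per_cell, summary)


def normalize(adata: AnnData, scale_target: float = 10_000.0) -> AnnData:
    """Depth-scaled log1p normalization.

    Returns a new AnnData whose X is ``ln(1 + count * scale_target /
    cell_total)``; zeros stay zero and per-cell values are monotone in the
    raw counts. Cells with zero total counts are rejected (run
    :func:`filter_cells` first).
    """
    if scale_target <= 0:
        raise ValueError("scale_target must be positive")
    out = adata.copy()
    X = out.X
    if sparse.issparse(X):
        X = X.tocsr().astype(np.float64)
        totals = np.asarray(X.sum(axis=1)).ravel()
        if np.any(totals == 0):
            raise ValueError("zero-total cell encountered; apply QC filtering first")
        scale = scale_target / totals
        X = sparse.diags(scale) @ X
        X.data = np.log1p(X.data)
        out.X = X.tocsr()
    else:
        X = np.asarray(X, dtype=np.float64)
        totals = X.sum(axis=1)
        if np.any(totals == 0):
            raise ValueError("zero-total cell encountered; apply QC filtering first")
        out.X = np.log1p(X * (scale_target / totals)[:, None])
    return out
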