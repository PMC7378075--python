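"""Gene filtering and log transformation of the expression matrix.

Genes with zero expression in every cell carry no information that could
separate cell types, so they are removed before any distance is computed.
Cells are never removed. Expression values are then variance-stabilised with
log2(x + 1), which maps zeros to zeros — hence filtering and transforming
commute.
"""

from __future__ import annotations

import numpy as np

from .containers import ExpressionMatrix

__all__ = ["filter_unexpressed_genes", "log_transform"]


def filter_unexpressed_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes whose expression is zero in all cells.

    Returns a matrix containing exactly the rows of ``m`` with at least one
    strictly positive entry, original order preserved. Raises ``ValueError``
    if no gene is expressed anywhere.
    """
    expressed = np.any(m.values > 0, axis=1)
    if not expressed.any():
        raise ValueError(
            "all genes are unexpressed (zero in every cell); nothing to cluster"
        )
    keep = np.flatnonzero(expressed)
    return ExpressionMatrix(
        values=m.values[keep, :],
        gene_ids=[m.gene_ids[i] for i in keep],
        cell_ids=list(m.cell_ids),
    )


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Element-wise log2(x + 1); shape and identifiers unchanged."""
    return ExpressionMatrix(
        values=np.log2(m.values + 1.0),
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
    )
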