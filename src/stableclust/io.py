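"""Readers and writers for expression matrices and label files.

Dense input is CSV/TSV with a header row of cell ids and gene ids in the
first column. Sparse input is MatrixMarket (.mtx) accompanied by two
one-column text files with gene and cell ids. Labels arrive either as a
two-column CSV (cell_id, label) or as a headerless one-label-per-line file
aligned to the matrix's cell order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io

from .containers import ExpressionMatrix

__all__ = [
    "read_dense",
    "read_mtx",
    "read_expression",
    "read_labels",
    "write_dense",
    "write_labels",
]


def read_dense(path, orientation: str = "gene_by_cell") -> ExpressionMatrix:
    """Read a dense CSV/TSV expression matrix.

    The delimiter is inferred from the suffix (.tsv/.txt -> tab, else
    comma). ``orientation="cell_by_gene"`` transposes on load.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "cell_by_gene":
        df = df.T
    elif orientation != "gene_by_cell":
        raise ValueError("orientation must be 'gene_by_cell' or 'cell_by_gene'")
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=[str(g) for g in df.index],
        cell_ids=[str(c) for c in df.columns],
    )


def _read_id_file(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_mtx(matrix_path, genes_path, cells_path,
             orientation: str = "gene_by_cell") -> ExpressionMatrix:
    """Read a MatrixMarket matrix plus one-column gene and cell id files."""
    values = np.asarray(scipy.io.mmread(matrix_path).todense(), dtype=float)
    if orientation == "cell_by_gene":
        values = values.T
    elif orientation != "gene_by_cell":
        raise ValueError("orientation must be 'gene_by_cell' or 'cell_by_gene'")
    return ExpressionMatrix(
        values=values,
        gene_ids=_read_id_file(genes_path),
        cell_ids=_read_id_file(cells_path),
    )


def read_expression(path, genes_path=None, cells_path=None,
                    orientation: str = "gene_by_cell") -> ExpressionMatrix:
    """Dispatch on suffix: .mtx needs id files, anything else is dense."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        if genes_path is None or cells_path is None:
            raise ValueError(".mtx input requires gene and cell id files")
        return read_mtx(path, genes_path, cells_path, orientation)
    return read_dense(path, orientation)


def read_labels(path, cell_ids: list[str] | None = None) -> np.ndarray:
    """Read ground-truth labels, one per cell.

    A two-column file (cell_id, label) is reordered to match ``cell_ids``;
    a one-column file is taken as already aligned to the matrix's cell
    order.
    """
    df = pd.read_csv(path, header=None, dtype=str)
    if df.iloc[0, 0] == "cell_id":  # tolerate a header row
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] == 1:
        return df.iloc[:, 0].to_numpy()
    if df.shape[1] == 2:
        mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        if cell_ids is None:
            return df.iloc[:, 1].to_numpy()
        missing = [c for c in cell_ids if c not in mapping]
        if missing:
            raise ValueError(f"labels missing for {len(missing)} cells "
                             f"(first: {missing[0]})")
        return np.asarray([mapping[c] for c in cell_ids])
    raise ValueError("label file must have one or two columns")


def write_dense(m: ExpressionMatrix, path) -> None:
    m.to_dataframe().to_csv(path)


def write_labels(labels, cell_ids, path) -> None:
    pd.DataFrame({"cell_id": cell_ids, "label": labels}).to_csv(path, index=False)
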