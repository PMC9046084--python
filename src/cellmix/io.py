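"""Readers and writers for the package's on-disk formats.

Single-cell input is accepted either as MatrixMarket sparse counts with
side files for gene and cell ids, or as a dense TSV/CSV with a header
row of genes.  Labels are two-column CSV (cell_id, label).  All derived
matrices (references, fractions, per-type expression) are written as
plain CSV with an id index.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .gibbs import BulkExpression


def read_sc_counts_mtx(mtx_path, genes_path, cells_path):
    """Read cells x genes counts from MatrixMarket plus id side files.

    The matrix may be stored either orientation; it is transposed when
    the row count matches the gene list instead of the cell list.
    Returns ``(counts ndarray, cell_ids, gene_ids)``.
    """
    mat = spio.mmread(mtx_path)
    if sparse.issparse(mat):
        mat = mat.toarray()
    genes = pd.read_csv(genes_path, header=None).iloc[:, 0].astype(str).to_numpy()
    cells = pd.read_csv(cells_path, header=None).iloc[:, 0].astype(str).to_numpy()
    if mat.shape == (len(genes), len(cells)) and mat.shape[0] != mat.shape[1]:
        mat = mat.T
    if mat.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix shape {mat.shape} matches neither (cells, genes)="
            f"({len(cells)}, {len(genes)}) nor its transpose"
        )
    return np.asarray(mat), cells, genes


def write_sc_counts_mtx(out_dir, counts, cell_ids, gene_ids, prefix="sc"):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out_dir / f"{prefix}_counts.mtx", sparse.csr_matrix(counts))
    pd.Series(list(gene_ids)).to_csv(out_dir / f"{prefix}_genes.tsv",
                                     index=False, header=False)
    pd.Series(list(cell_ids)).to_csv(out_dir / f"{prefix}_cells.tsv",
                                     index=False, header=False)


def read_labels_csv(path) -> pd.Series:
    """Two-column CSV (cell_id, label) -> Series indexed by cell id."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("label file needs two columns: cell_id, label")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))


def read_bulk_table(path) -> BulkExpression:
    """Dense TSV/CSV bulk matrix: rows = samples, header row = genes."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return BulkExpression(
        X=df.to_numpy(),
        sample_ids=[str(s) for s in df.index],
        gene_ids=df.columns.to_numpy(dtype=object),
    )


def write_bulk_table(path, bulk: BulkExpression) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    pd.DataFrame(bulk.X, index=bulk.sample_ids, columns=bulk.gene_ids).to_csv(
        path, sep=sep
    )


def write_matrix_csv(path, matrix, row_ids, col_ids) -> None:
    pd.DataFrame(np.asarray(matrix), index=list(row_ids),
                 columns=list(col_ids)).to_csv(path)


def read_matrix_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
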