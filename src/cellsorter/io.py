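"""File input/output for expression matrices, marker tables and HVG lists.

Two expression formats are supported: a dense delimited file (first column
gene ids, header row of cell ids, genes in rows by default) and the 10x-style
MatrixMarket triplet (``matrix.mtx`` plus ``genes.tsv`` and ``barcodes.tsv``
companions in the same directory).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import ExpressionMatrix

__all__ = [
    "load_expression",
    "load_markers",
    "load_hvg",
    "write_dense",
    "write_mtx",
    "write_labels",
]


def _read_companion(path: str) -> list[str]:
    with open(path) as fh:
        # genes.tsv may carry extra columns (ensembl id, symbol); keep col 0
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def load_expression(
    path: str,
    format: str = "dense",
    cells_in_rows: bool = False,
    is_lognorm: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    Parameters
    ----------
    path
        Dense: the delimited file. MatrixMarket (``format="mtx"``): the
        ``.mtx`` file, with ``genes.tsv`` and ``barcodes.tsv`` alongside.
    format
        ``"dense"`` or ``"mtx"``.
    cells_in_rows
        Dense files are assumed genes-in-rows; set True to transpose.
    is_lognorm
        Mark values as already log-normalized.
    """
    if format == "dense":
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep, index_col=0)

        def _unparseable(v) -> bool:
            try:
                float(v)
                return False
            except (TypeError, ValueError):
                return True

        bad = df.map(_unparseable)
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"non-numeric entry at row '{df.index[r]}', column '{df.columns[c]}'"
            )
        df = df.astype(float)
        if cells_in_rows:
            df = df.T
        return ExpressionMatrix(
            df.to_numpy(dtype=float),
            list(df.index.astype(str)),
            list(df.columns.astype(str)),
            is_lognorm=is_lognorm,
        )
    if format == "mtx":
        mat = scipy.io.mmread(path)
        d = os.path.dirname(path) or "."
        genes = _read_companion(os.path.join(d, "genes.tsv"))
        barcodes = _read_companion(os.path.join(d, "barcodes.tsv"))
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        if dense.shape != (len(genes), len(barcodes)):
            if dense.shape == (len(barcodes), len(genes)):
                dense = dense.T
            else:
                raise ValueError(
                    f"matrix shape {dense.shape} matches neither "
                    f"{len(genes)} genes x {len(barcodes)} barcodes nor its transpose"
                )
        return ExpressionMatrix(dense, genes, barcodes, is_lognorm=is_lognorm)
    raise ValueError(f"unknown format {format!r}; use 'dense' or 'mtx'")


def load_markers(path: str) -> pd.DataFrame:
    """Read a marker table (columns ``type,gene[,weight]``, CSV or TSV)."""
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.lower() for c in df.columns]
    if not {"type", "gene"}.issubset(df.columns):
        raise ValueError(f"{path}: marker table needs 'type' and 'gene' columns")
    return df


def load_hvg(path: str) -> list[str]:
    """Read a highly-variable-gene list, one gene id per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_dense(expr: ExpressionMatrix, path: str) -> None:
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    expr.to_frame().to_csv(path, sep=sep)


def write_mtx(expr: ExpressionMatrix, dir: str, name: str = "matrix.mtx") -> str:
    """Write the 10x-style triplet (mtx + genes.tsv + barcodes.tsv)."""
    os.makedirs(dir, exist_ok=True)
    path = os.path.join(dir, name)
    scipy.io.mmwrite(path, scipy.sparse.coo_matrix(expr.values))
    with open(os.path.join(dir, "genes.tsv"), "w") as fh:
        fh.writelines(g + "\n" for g in expr.gene_ids)
    with open(os.path.join(dir, "barcodes.tsv"), "w") as fh:
        fh.writelines(c + "\n" for c in expr.cell_ids)
    return path


def write_labels(cell_ids: list[str], labels: list[str], path: str) -> None:
    """Write the per-cell label TSV with header ``cell_id<TAB>label``."""
    pd.DataFrame({"cell_id": cell_ids, "label": labels}).to_csv(
        path, sep="\t", index=False
    )
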