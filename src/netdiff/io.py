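"""Plain-text (TSV) readers and writers for expression, networks and edges.

All artifacts are tab-separated text with one header row and one label
column.  Expression matrices default to samples x genes (one row per
sample); a flag transposes genes x samples files on read.  Coefficient
and adjacency matrices are p x p with gene labels on both axes; entry
(row j, column i) is the effect of gene j on gene i.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_matrix",
    "write_matrix",
    "write_edge_table",
    "read_edge_table",
]


def read_expression_matrix(path, genes_in_rows: bool = False) -> pd.DataFrame:
    """Read a labeled expression TSV; validate finiteness.

    Expects one header row and one label column.  With ``genes_in_rows``
    the file is genes x samples and is transposed to samples x genes.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no data columns")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-finite value at row '{df.index[r]}', column '{df.columns[c]}'"
        )
    if genes_in_rows:
        df = df.T
    return df.astype(float)


def write_expression_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    """Read a gene-labeled square matrix TSV (adjacency or coefficients)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: non-finite entries")
    return df.astype(float)


def write_matrix(matrix: np.ndarray, labels, path) -> None:
    pd.DataFrame(np.asarray(matrix), index=labels, columns=labels).to_csv(path, sep="\t")


def write_edge_table(table: pd.DataFrame, path) -> None:
    """Write a ranked changed-edge table (source regulates target, b[j, i])."""
    cols = ["source_gene", "target_gene", "b", "b_tilde", "delta_b", "delta_r"]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"edge table missing columns: {missing}")
    table[cols].to_csv(path, sep="\t", index=False)


def read_edge_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
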