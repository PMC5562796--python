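"""Matrix and table I/O for the pipeline.

Expression matrices are genes x samples (or genes x cells) everywhere;
both dense TSV/CSV and sparse Matrix Market (MTX) triplets with side files
of row and column labels are supported.  Values must be finite and
non-negative, labels unique.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse


__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotations",
    "read_conditions",
    "read_infiltration",
]


def _validate(matrix: pd.DataFrame) -> pd.DataFrame:
    if matrix.index.duplicated().any():
        dups = list(matrix.index[matrix.index.duplicated()].unique()[:10])
        raise ValueError(f"duplicate gene symbols: {dups}")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate sample/cell labels")
    values = matrix.to_numpy(float)
    if np.isnan(values).any():
        raise ValueError("matrix contains NaN values")
    if not np.isfinite(values).all():
        raise ValueError("matrix contains non-finite values")
    if (values < 0).any():
        raise ValueError("matrix contains negative values")
    return matrix


def read_expression_matrix(
    path: str | Path,
    fmt: str | None = None,
    transpose: bool = False,
    genes_path: str | Path | None = None,
    samples_path: str | Path | None = None,
) -> pd.DataFrame:
    """Read a genes x samples expression matrix.

    ``fmt`` is one of ``tsv``, ``csv``, ``mtx`` (inferred from the suffix
    when omitted).  For MTX, ``genes_path`` / ``samples_path`` default to
    ``genes.tsv`` / ``barcodes.tsv`` next to the matrix.  ``transpose``
    flips a samples x genes file into the canonical orientation.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower()
        )
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix of {path.name}")
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        matrix = pd.read_csv(path, sep=sep, index_col=0)
    elif fmt == "mtx":
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        samples_path = (
            Path(samples_path) if samples_path else path.parent / "barcodes.tsv"
        )
        m = sio.mmread(path)
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].tolist()
        cols = pd.read_csv(samples_path, sep="\t", header=None)[0].tolist()
        dense = m.toarray() if sparse.issparse(m) else np.asarray(m)
        matrix = pd.DataFrame(dense, index=genes, columns=cols)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if transpose:
        matrix = matrix.T
    matrix.index = matrix.index.astype(str)
    matrix.index.name = "gene"
    return _validate(matrix)


def write_expression_matrix(
    matrix: pd.DataFrame, path: str | Path, fmt: str | None = None
) -> None:
    """Write a genes x samples matrix as TSV/CSV or MTX triplet."""
    path = Path(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "tsv"
        )
    if fmt in ("tsv", "csv"):
        matrix.to_csv(path, sep="\t" if fmt == "tsv" else ",")
    elif fmt == "mtx":
        sio.mmwrite(str(path), sparse.csr_matrix(matrix.to_numpy()))
        pd.Series(matrix.index).to_csv(
            path.parent / "genes.tsv", sep="\t", index=False, header=False
        )
        pd.Series(matrix.columns).to_csv(
            path.parent / "barcodes.tsv", sep="\t", index=False, header=False
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_annotations(path: str | Path) -> pd.Series:
    """Read a cell -> cell-type annotation TSV (2 columns, header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.iloc[0, 1].strip().lower() in ("cell_type", "type", "celltype"):
        df = df.iloc[1:]
    return pd.Series(df[1].to_numpy(), index=df[0].to_numpy(), name="cell_type")


def read_conditions(path: str | Path) -> pd.Series:
    """Read a sample -> condition ('normal'/'cancer') TSV."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.iloc[0, 1].strip().lower() == "condition":
        df = df.iloc[1:]
    cond = pd.Series(df[1].str.strip().to_numpy(), index=df[0].to_numpy(), name="condition")
    bad = set(cond.unique()) - {"normal", "cancer"}
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    return cond


def read_infiltration(path: str | Path) -> pd.DataFrame:
    """Read a sample x {lymphocyte, monocyte, neutrophil, stromal} TSV."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    values = table.to_numpy(float)
    if ((values < 0) | (values > 1)).any():
        raise ValueError("infiltration fractions must lie in [0, 1]")
    return table
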