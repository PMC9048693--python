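"""Readers and writers for count matrices and model artifacts.

The primary on-disk format is delimited text (tab by default): genes as
rows with identifiers in the first column, a header row of sample
identifiers.  Lines starting with '#' are provenance comments and are
ignored on read.  Matrix-market triplet files with sidecar row/column
identifier files (one id per line) are supported for sparse data.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import CountMatrix
from .correct import CorrectionTable
from .matching import WeightMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_coefficients",
    "write_coefficients",
    "write_weights",
    "write_factors",
]


def _provenance(params: dict | None = None) -> str:
    extra = "" if not params else " " + " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"# poibm v{__version__}{extra}"


def read_counts(
    path,
    delimiter: str = "\t",
    strict: bool = False,
    gene_file=None,
    sample_file=None,
) -> CountMatrix:
    """Read a count matrix from delimited text or matrix-market triplets.

    Matrix-market input (``.mtx`` suffix) requires sidecar identifier
    files ``gene_file`` and ``sample_file`` (defaulting to
    ``<path>.genes.txt`` / ``<path>.samples.txt``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        raw = mmread(str(path))
        counts = np.asarray(raw.todense() if hasattr(raw, "todense") else raw, dtype=float)
        gene_file = Path(gene_file) if gene_file else path.with_suffix(".mtx.genes.txt")
        sample_file = Path(sample_file) if sample_file else path.with_suffix(".mtx.samples.txt")
        gene_ids = [ln.strip() for ln in gene_file.read_text().splitlines() if ln.strip()]
        sample_ids = [ln.strip() for ln in sample_file.read_text().splitlines() if ln.strip()]
        return CountMatrix(counts, np.asarray(gene_ids, object), np.asarray(sample_ids, object), strict=strict)

    try:
        frame = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"{path}: malformed count matrix: {exc}") from exc
    if frame.shape[1] < 1:
        raise ValueError(f"{path}: no sample columns found (wrong delimiter?)")
    if frame.isna().any().any():
        gene = frame.index[frame.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing value in row for gene {gene!r}")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric entries in count matrix")
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative count for gene {frame.index[i]!r}, sample {frame.columns[j]!r}"
        )
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene identifier {dup!r}")
    if frame.columns.duplicated().any():
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample identifier {dup!r}")
    return CountMatrix.from_frame(frame, strict=strict)


def write_counts(matrix: CountMatrix, path, delimiter: str = "\t", params: dict | None = None) -> None:
    """Write a count matrix as delimited text with a provenance header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance(params) + "\n")
        matrix.to_frame().to_csv(fh, sep=delimiter, index_label="gene_id")


def write_coefficients(table: CorrectionTable, path, delimiter: str = "\t") -> None:
    """Two-column coefficient table (gene id, coefficient) with batch labels."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance({"target": table.target_batch_label, "source": table.source_batch_label}) + "\n")
        fh.write(f"gene_id{delimiter}coefficient\n")
        for g, c in zip(table.gene_ids, table.c):
            fh.write(f"{g}{delimiter}{float(c)!r}\n")


def read_coefficients(path, delimiter: str = "\t") -> CorrectionTable:
    path = Path(path)
    target_label, source_label = "target", "source"
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            if tok.startswith("target="):
                target_label = tok.split("=", 1)[1]
            elif tok.startswith("source="):
                source_label = tok.split("=", 1)[1]
    frame = pd.read_csv(path, sep=delimiter, comment="#")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene id, coefficient)")
    return CorrectionTable(
        frame.iloc[:, 0].to_numpy(dtype=object),
        frame.iloc[:, 1].to_numpy(dtype=float),
        target_batch_label=target_label,
        source_batch_label=source_label,
    )


def write_weights(weights: WeightMatrix, target_ids, source_ids, path, delimiter: str = "\t") -> None:
    """Weight matrix as delimited text: target ids as rows, source ids as columns."""
    frame = pd.DataFrame(weights.w, index=target_ids, columns=source_ids)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance() + "\n")
        frame.to_csv(fh, sep=delimiter, index_label="target_id")


def write_factors(v: np.ndarray, sample_ids, path, delimiter: str = "\t") -> None:
    """Per-sample total-RNA factors as two-column delimited text."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance() + "\n")
        fh.write(f"sample_id{delimiter}factor\n")
        for s, val in zip(sample_ids, v):
            fh.write(f"{s}{delimiter}{float(val)!r}\n")


def log(message: str) -> None:
    print(message, file=sys.stderr)
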