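"""Applying fitted batch coefficients to count matrices.

Correction is gene-wise multiplicative: ``Yhat_ij = c_i * Y_ij`` maps the
source batch into the target space.  Because the coefficients are explicit
per gene, out-of-sample correction of future data from the same source
batch is a plain table lookup.  Output is real-valued by default (the
transform does not preserve integrality); rounding is opt-in and lossy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import CountMatrix, PoibmModel

__all__ = [
    "CorrectionTable",
    "table_from_model",
    "apply_correction",
    "invert_correction",
    "split_correction",
]


@dataclass(frozen=True)
class CorrectionTable:
    """Per-gene batch coefficients mapping source-space data to target space."""

    gene_ids: np.ndarray
    c: np.ndarray
    target_batch_label: str = "target"
    source_batch_label: str = "source"

    def __post_init__(self) -> None:
        gene_ids = np.asarray(self.gene_ids, dtype=object)
        c = np.asarray(self.c, dtype=float)
        if gene_ids.size != c.size:
            raise ValueError("gene_ids and coefficients differ in length")
        if np.any(~np.isfinite(c)) or np.any(c <= 0):
            raise ValueError("coefficients must be strictly positive and finite")
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "c", c)

    def as_dict(self) -> dict:
        return dict(zip(self.gene_ids.tolist(), self.c.tolist()))


def table_from_model(
    model: PoibmModel,
    full_gene_ids=None,
    target_batch_label: str = "target",
    source_batch_label: str = "source",
) -> CorrectionTable:
    """Build a coefficient table from a fitted model.

    When ``full_gene_ids`` is given (the caller's complete gene set,
    including genes dropped during alignment), genes absent from the fit
    receive the no-op coefficient 1 so the corrected matrix keeps the full
    gene set without bias.
    """
    if model.gene_ids is None:
        raise ValueError("model carries no gene identifiers")
    if full_gene_ids is None:
        return CorrectionTable(model.gene_ids, model.c, target_batch_label, source_batch_label)
    full_gene_ids = np.asarray(full_gene_ids, dtype=object)
    lookup = dict(zip(model.gene_ids.tolist(), model.c.tolist()))
    c = np.array([lookup.get(g, 1.0) for g in full_gene_ids], dtype=float)
    return CorrectionTable(full_gene_ids, c, target_batch_label, source_batch_label)


def apply_correction(
    Y: CountMatrix, table: CorrectionTable, rounding: bool = False
) -> CountMatrix:
    """Map a source-batch matrix into the target space, ``Yhat = c * Y``.

    Genes of ``Y`` missing from the table get coefficient 1 with a warning.
    With ``rounding=True`` the output is the nearest non-negative integer.
    """
    lookup = table.as_dict()
    missing = [g for g in Y.gene_ids if g not in lookup]
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) missing from correction table; using c = 1",
            stacklevel=2,
        )
    c = np.array([lookup.get(g, 1.0) for g in Y.gene_ids], dtype=float)
    corrected = c[:, None] * Y.counts
    if rounding:
        corrected = np.maximum(np.round(corrected), 0.0)
    return CountMatrix(corrected, Y.gene_ids, Y.sample_ids)


def invert_correction(table: CorrectionTable) -> CorrectionTable:
    """Reciprocal coefficients with batch labels swapped: maps target-space
    data back into the source space."""
    return CorrectionTable(
        table.gene_ids,
        1.0 / table.c,
        target_batch_label=table.source_batch_label,
        source_batch_label=table.target_batch_label,
    )


def split_correction(
    table: CorrectionTable, exponent: float = 0.5
) -> tuple[CorrectionTable, CorrectionTable]:
    """Split the correction so both batches map into a common space.

    Returns ``(for_source, for_target)`` with coefficients ``c**exponent``
    and ``c**(exponent - 1)``; the default 0.5 places both batches in the
    geometric-mean space.  ``exponent=1`` recovers the plain target-space
    mapping (source table = c, target table = identity).
    """
    common = f"common(e={exponent:g})"
    for_source = CorrectionTable(
        table.gene_ids, table.c**exponent, common, table.source_batch_label
    )
    for_target = CorrectionTable(
        table.gene_ids, table.c ** (exponent - 1.0), common, table.target_batch_label
    )
    return for_source, for_target
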