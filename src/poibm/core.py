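"""Core domain types: count matrices, fitted models, fit configuration.

A batch of RNA-seq data is modelled as ``X_ij ~ Poisson(c_i * u_ij * v_j)``
where ``c_i`` are gene-wise multiplicative batch coefficients, ``u_ij`` the
underlying batch-free expression profiles and ``v_j`` per-sample total-RNA
(library size) factors.  These types carry the data and parameters of that
model; the estimation lives in :mod:`poibm.em`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CountMatrix",
    "PoibmModel",
    "FitConfig",
    "AlignmentReport",
    "validate_pair",
]

#: numerical floor applied to model parameters so logarithms stay finite
PARAM_FLOOR = 1e-12


def _as_id_array(ids: Sequence[str], what: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if arr.ndim != 1:
        raise ValueError(f"{what} must be one-dimensional")
    if len(set(arr.tolist())) != arr.size:
        raise ValueError(f"duplicate {what} found")
    return arr


@dataclass(frozen=True)
class CountMatrix:
    """A gene x sample matrix of read counts with identifiers.

    Parameters
    ----------
    counts
        Non-negative matrix, shape ``(m_genes, n_samples)``.  Stored as
        float64 internally; with ``strict=True`` non-integer input is
        rejected (upstream quantifiers such as RSEM emit fractional
        expected counts, so the default is lenient).
    gene_ids, sample_ids
        Unique string identifiers for rows and columns.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    strict: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if counts.shape[0] < 1 or counts.shape[1] < 1:
            raise ValueError("counts must have at least one gene and one sample")
        if not np.all(np.isfinite(counts)):
            raise ValueError("counts contain non-finite values")
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise ValueError(f"negative count at gene index {i}, sample index {j}")
        if self.strict and not np.allclose(counts, np.round(counts)):
            i, j = np.argwhere(~np.isclose(counts, np.round(counts)))[0]
            raise ValueError(f"non-integer count at gene index {i}, sample index {j}")
        gene_ids = _as_id_array(self.gene_ids, "gene identifiers")
        sample_ids = _as_id_array(self.sample_ids, "sample identifiers")
        if gene_ids.size != counts.shape[0]:
            raise ValueError("gene_ids length does not match counts")
        if sample_ids.size != counts.shape[1]:
            raise ValueError("sample_ids length does not match counts")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "sample_ids", sample_ids)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, index: np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to the given gene row indices."""
        return CountMatrix(self.counts[index, :], self.gene_ids[index], self.sample_ids)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame, strict: bool = False) -> "CountMatrix":
        return cls(
            frame.to_numpy(dtype=float),
            frame.index.to_numpy(dtype=object),
            frame.columns.to_numpy(dtype=object),
            strict=strict,
        )


@dataclass(frozen=True)
class FitConfig:
    """Tuning parameters of the EM fit.

    ``rho_x`` / ``rho_y`` are the fractions of target / source samples kept
    active by trimming; values below 1 protect against batch-unique
    subpopulations biasing the correction.  Defaults follow the method's
    standard settings: 100 iterations, 20 restarts and 50% trimming.
    """

    rho_x: float = 0.5
    rho_y: float = 0.5
    max_iter: int = 100
    n_restarts: int = 20
    tol: float = 1e-8
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("rho_x", "rho_y"):
            rho = getattr(self, name)
            if not (0.0 < rho <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {rho}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be positive")
        if not (self.tol > 0):
            raise ValueError("tol must be positive")


@dataclass
class PoibmModel:
    """Fitted parameters of the sample-matching batch model.

    Attributes
    ----------
    c
        Gene-wise batch coefficients mapping source to target space, length m.
    u
        Shared expression profiles of the matched pairs, shape (m, n_y).
    v_x, v_y
        Total-RNA factors of target and source samples.
    w
        Matching weights, shape (n_x, n_y); each active source column sums
        to 1, active target rows carry equal mass (balanced convention).
    active_targets, active_sources
        Boolean trimming masks over target / source samples.
    objective
        Final value of the EM objective (expected Poisson log-likelihood
        against the saturated model, plus the matching-entropy term).
    """

    c: np.ndarray
    u: np.ndarray
    v_x: np.ndarray
    v_y: np.ndarray
    w: np.ndarray
    active_targets: np.ndarray
    active_sources: np.ndarray
    objective: float
    n_iter: int
    converged: bool
    gene_ids: np.ndarray | None = None

    def validate(self) -> None:
        for name in ("c", "u", "v_x", "v_y"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"model parameter {name} must be strictly positive and finite")
        if np.any(self.w < 0) or not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite and non-negative")
        if not np.isfinite(self.objective):
            raise ValueError("objective must be finite")


@dataclass(frozen=True)
class AlignmentReport:
    """What :func:`validate_pair` removed while aligning two batches."""

    n_genes_kept: int
    n_dropped_target_only: int
    n_dropped_source_only: int
    n_dropped_all_zero: int
    dropped_all_zero_ids: tuple = ()


def validate_pair(
    target: CountMatrix, source: CountMatrix
) -> tuple[CountMatrix, CountMatrix, AlignmentReport]:
    """Align two count matrices on their shared gene set.

    Restricts both matrices to the intersection of their gene identifiers
    (exact string match), in a common order, and removes genes with zero
    counts across all samples of either batch.  The returned report states
    how many genes were dropped from each side and by the all-zero filter.

    Idempotent: applying it to its own output changes nothing.
    """
    tgt_index = {g: i for i, g in enumerate(target.gene_ids)}
    shared = [g for g in source.gene_ids if g in tgt_index]
    if not shared:
        raise ValueError("no genes shared between target and source matrices")
    # order by target appearance for a deterministic common order
    shared.sort(key=lambda g: tgt_index[g])
    src_index = {g: i for i, g in enumerate(source.gene_ids)}
    tgt_rows = np.array([tgt_index[g] for g in shared], dtype=int)
    src_rows = np.array([src_index[g] for g in shared], dtype=int)

    tgt_counts = target.counts[tgt_rows, :]
    src_counts = source.counts[src_rows, :]
    nonzero = (tgt_counts.sum(axis=1) > 0) & (src_counts.sum(axis=1) > 0)
    if not np.any(nonzero):
        raise ValueError("all shared genes have zero counts in one of the batches")

    kept_ids = np.asarray(shared, dtype=object)[nonzero]
    dropped_zero = tuple(np.asarray(shared, dtype=object)[~nonzero].tolist())
    report = AlignmentReport(
        n_genes_kept=int(nonzero.sum()),
        n_dropped_target_only=target.n_genes - len(shared),
        n_dropped_source_only=source.n_genes - len(shared),
        n_dropped_all_zero=int((~nonzero).sum()),
        dropped_all_zero_ids=dropped_zero,
    )
    aligned_target = CountMatrix(tgt_counts[nonzero, :], kept_ids, target.sample_ids)
    aligned_source = CountMatrix(src_counts[nonzero, :], kept_ids, source.sample_ids)
    return aligned_target, aligned_source, report
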