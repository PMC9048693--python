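"""Evaluation metrics for batch correction quality.

Corrected and uncorrected matrices are compared on counts-per-million,
log-transformed data: per-gene one-way ANOVA gives the fraction of
variance explained by batch, condition, or their crossing; Bartlett's
test compares the spread of those fractions between methods; PCA
projections visualize sample structure; a box-kernel density summarizes
the fraction distributions.  Between fitted batch pairs, the magnitude of
the log batch coefficients yields a directed dissimilarity (mean
fold-change) that can be clustered hierarchically.  Matching diagnostics
(weight on known pairs, mapping perplexity) quantify replicate discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .correct import CorrectionTable
from .matching import WeightMatrix, effective_targets

__all__ = [
    "EvalReport",
    "BatchDistanceMatrix",
    "cpm_log",
    "explained_variance",
    "bartlett_compare",
    "density_estimate",
    "pca_project",
    "batch_distance",
    "matching_report",
]


def cpm_log(
    counts: np.ndarray, base: float = 2.0, pseudocount: float = 1.0, scale: float = 1e6
) -> np.ndarray:
    """Counts-per-million, log-transformed: ``log_base(pseudocount + scale * x / colsum)``."""
    counts = np.asarray(counts, dtype=float)
    colsum = counts.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("zero column sum; cannot scale to CPM")
    cpm = scale * counts / colsum[None, :]
    return np.log(pseudocount + cpm) / np.log(base)


def _fraction_one_factor(data: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-gene between-group sum of squares over total sum of squares."""
    labels = np.asarray(labels)
    levels, inverse = np.unique(labels, return_inverse=True)
    if levels.size < 2:
        raise ValueError("factor needs at least two levels")
    n = data.shape[1]
    grand = data.mean(axis=1, keepdims=True)
    sst = ((data - grand) ** 2).sum(axis=1)
    ssb = np.zeros(data.shape[0])
    for lv in range(levels.size):
        cols = inverse == lv
        nk = cols.sum()
        group_mean = data[:, cols].mean(axis=1)
        ssb += nk * (group_mean - grand[:, 0]) ** 2
    frac = np.zeros(data.shape[0])
    nz = sst > 0
    frac[nz] = ssb[nz] / sst[nz]  # constant genes -> 0 by definition
    return np.clip(frac, 0.0, 1.0)


def explained_variance(
    data: np.ndarray,
    batch: np.ndarray | None = None,
    condition: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene fraction of variance explained by labeled factors.

    Columns: one per supplied factor among ``condition``, ``batch`` and,
    when both are given, ``both`` — the crossed grouping of unique
    (batch, condition) combinations.  Values lie in [0, 1]; the mean over
    genes is the table-level summary (``frame.mean()``).
    """
    data = np.asarray(data, dtype=float)
    out = {}
    if condition is not None:
        out["condition"] = _fraction_one_factor(data, np.asarray(condition))
    if batch is not None:
        out["batch"] = _fraction_one_factor(data, np.asarray(batch))
    if batch is not None and condition is not None:
        crossed = np.array([f"{b}\x00{c}" for b, c in zip(batch, condition)])
        out["both"] = _fraction_one_factor(data, crossed)
    if not out:
        raise ValueError("supply at least one factor")
    return pd.DataFrame(out)


def bartlett_compare(
    fractions_a: np.ndarray, fractions_b: np.ndarray, tail: str = "less"
) -> tuple[float, float]:
    """Bartlett's equal-variance test between two sets of per-gene values.

    ``tail='less'`` reports evidence that set *a* has smaller variance than
    set *b* (the direction of interest when *a* is a corrected method and
    *b* the unadjusted data); ``'greater'`` the reverse; ``'two-sided'``
    the plain test.  Returns ``(statistic, p_value)``.
    """
    a = np.asarray(fractions_a, dtype=float)
    b = np.asarray(fractions_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per set")
    if np.var(a, ddof=1) == 0 or np.var(b, ddof=1) == 0:
        raise ValueError("zero variance in one of the sets")
    stat, p_two = stats.bartlett(a, b)
    if tail == "two-sided":
        return float(stat), float(p_two)
    a_smaller = np.var(a, ddof=1) < np.var(b, ddof=1)
    matches = a_smaller if tail == "less" else not a_smaller
    if tail not in ("less", "greater"):
        raise ValueError("tail must be 'less', 'greater' or 'two-sided'")
    p = p_two / 2.0 if matches else 1.0 - p_two / 2.0
    return float(stat), float(p)


def density_estimate(
    values: np.ndarray,
    bandwidth: float = 0.02,
    grid_size: int = 512,
    support: tuple = (0.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Box-kernel density on a uniform grid over the support.

    Each observation contributes a rectangle of half-width ``bandwidth``;
    the curve is renormalized to integrate to 1 over the grid (boundary
    correction for mass that would fall outside the support).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.linspace(support[0], support[1], grid_size)
    inside = np.abs(grid[None, :] - values[:, None]) <= bandwidth
    density = inside.mean(axis=0) / (2.0 * bandwidth)
    total = np.trapezoid(density, grid)
    if total > 0:
        density = density / total
    return grid, density


def pca_project(data: np.ndarray, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Sample-space PCA of a genes x samples matrix (mean-centered by gene).

    Returns ``(scores, explained_ratios)`` with scores of shape
    ``(n_samples, n_components)``.
    """
    data = np.asarray(data, dtype=float)
    centered = (data - data.mean(axis=1, keepdims=True)).T  # samples x genes
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    ratios = var / var.sum() if var.sum() > 0 else var
    k = min(n_components, s.size)
    return u[:, :k] * s[:k], ratios[:k]


@dataclass
class EvalReport:
    """Bundle of evaluation outputs for one corrected/uncorrected matrix."""

    fractions: pd.DataFrame
    mean_fractions: pd.Series
    pca_scores: np.ndarray
    pca_explained: np.ndarray
    densities: dict = field(default_factory=dict)


def evaluate_matrix(
    counts: np.ndarray,
    batch: np.ndarray | None = None,
    condition: np.ndarray | None = None,
    bandwidth: float = 0.02,
    n_components: int = 2,
) -> EvalReport:
    """CPM-log transform, explained variance, PCA and fraction densities."""
    logdata = cpm_log(counts)
    fractions = explained_variance(logdata, batch=batch, condition=condition)
    scores, ratios = pca_project(logdata, n_components=n_components)
    densities = {
        col: density_estimate(fractions[col].to_numpy(), bandwidth=bandwidth)
        for col in fractions.columns
    }
    return EvalReport(
        fractions=fractions,
        mean_fractions=fractions.mean(),
        pca_scores=scores,
        pca_explained=ratios,
        densities=densities,
    )


@dataclass
class BatchDistanceMatrix:
    """Directed batch dissimilarities as mean coefficient fold-changes."""

    labels: list
    fold_changes: pd.DataFrame  # directed, diagonal 1
    linkage: np.ndarray | None = None


def batch_distance(tables: dict) -> BatchDistanceMatrix:
    """Mean batch-coefficient fold-changes between batches, with clustering.

    ``tables`` maps ``(target_label, source_label)`` to a
    :class:`~poibm.correct.CorrectionTable` over a common gene set.  The
    dissimilarity is ``exp(mean_i |log c_i|)`` (a fold-change >= 1; 1 means
    no batch effect), symmetric under swapping the direction when the
    coefficients invert.  Hierarchical clustering uses average linkage on
    the direction-averaged log fold-changes.
    """
    labels = sorted({lab for pair in tables for lab in pair})
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    log_fc = np.zeros((n, n))
    seen = np.eye(n, dtype=bool)
    for (tgt, src), table in tables.items():
        d = float(np.mean(np.abs(np.log(table.c))))
        log_fc[idx[tgt], idx[src]] = d
        seen[idx[tgt], idx[src]] = True
        if not seen[idx[src], idx[tgt]]:  # fill reverse from |log c| symmetry
            log_fc[idx[src], idx[tgt]] = d
    fold = pd.DataFrame(np.exp(log_fc), index=labels, columns=labels)
    linkage = None
    if n > 2 or (n == 2 and seen.all()):
        sym = (log_fc + log_fc.T) / 2.0
        np.fill_diagonal(sym, 0.0)
        linkage = hierarchy.average(squareform(sym, checks=False))
    return BatchDistanceMatrix(labels=labels, fold_changes=fold, linkage=linkage)


def matching_report(
    weights: WeightMatrix,
    known_pairs: list | None = None,
    source_ids=None,
    target_ids=None,
) -> dict:
    """Diagnostics of a fitted matching.

    Per source sample: its perplexity in effective targets and its top
    match.  With ``known_pairs`` (list of (target index, source index)),
    also the fraction of total weight mass on the true pairs and the mean
    perplexity of paired versus unpaired sources.
    """
    n_x, n_y = weights.w.shape
    perplexity = np.array([effective_targets(weights, j) for j in range(n_y)])
    top = np.argmax(weights.w, axis=0)
    per_source = pd.DataFrame(
        {
            "active": weights.active_sources,
            "perplexity": perplexity,
            "top_target": top if target_ids is None else np.asarray(target_ids)[top],
            "top_weight": weights.w[top, np.arange(n_y)],
        },
        index=source_ids if source_ids is not None else np.arange(n_y),
    )
    report = {
        "per_source": per_source,
        "n_active_targets": weights.n_active_targets,
        "n_active_sources": weights.n_active_sources,
    }
    if known_pairs is not None:
        total = weights.w.sum()
        on_truth = sum(weights.w[k, j] for k, j in known_pairs)
        paired_sources = {j for _, j in known_pairs}
        paired = [j for j in range(n_y) if j in paired_sources]
        unpaired = [j for j in range(n_y) if j not in paired_sources]
        def mean_finite(idx):
            vals = perplexity[idx]
            vals = vals[np.isfinite(vals)]
            return float(vals.mean()) if vals.size else float("nan")

        report["weight_on_truth"] = float(on_truth / total) if total > 0 else float("nan")
        report["mean_perplexity_paired"] = mean_finite(paired)
        report["mean_perplexity_unpaired"] = mean_finite(unpaired)
    return report
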