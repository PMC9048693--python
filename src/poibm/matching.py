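"""Latent sample-matching weights.

Each source sample is matched to a *virtual* target sample, a convex
combination of target-batch samples.  The match quality of pair (k, j) is
the Poisson log-likelihood of target sample k and source sample j under the
shared profile ``u_.j``, measured against the saturated model, so every
energy is a negative deviance (<= 0).  Weights are the entropy-regularized
balanced-transport solution over those energies: exponentiate, then apply
alternating row/column rescaling until each active source column sums to 1
and each active target row carries equal mass ``n_active_sources /
n_active_targets``.  Trimming restricts the model to a fraction of samples
per batch so batch-unique phenotypes cannot bias the correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .core import CountMatrix, PoibmModel

__all__ = [
    "WeightMatrix",
    "match_energy",
    "poisson_pair_energy",
    "normalize_weights",
    "trim_weights",
    "effective_targets",
]

_SINKHORN_MAX_SWEEPS = 1000
_SINKHORN_TOL = 1e-10


@dataclass
class WeightMatrix:
    """Matching weights with their trimming masks.

    ``w[k, j]`` is the weight of target sample k in the virtual target of
    source sample j; rows/columns of trimmed samples are exactly zero.
    """

    w: np.ndarray
    active_targets: np.ndarray
    active_sources: np.ndarray

    @property
    def n_active_targets(self) -> int:
        return int(self.active_targets.sum())

    @property
    def n_active_sources(self) -> int:
        return int(self.active_sources.sum())


def _check_positive(name: str, arr: np.ndarray) -> None:
    arr = np.asarray(arr)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"model parameter {name!r} must be strictly positive and finite")


def poisson_pair_energy(
    X: np.ndarray,
    Y: np.ndarray,
    c: np.ndarray,
    u: np.ndarray,
    v_x: np.ndarray,
    v_y: np.ndarray,
) -> np.ndarray:
    """Log match energy for every (target k, source j) pair.

    Returns the ``n_x x n_y`` matrix

    ``l_kj = sum_i [ X_ik log(c_i u_ij v_xk) - c_i u_ij v_xk
                     + Y_ij log(u_ij v_yj) - u_ij v_yj
                     - (X_ik log X_ik - X_ik) - (Y_ij log Y_ij - Y_ij) ]``

    with the convention ``0 log 0 = 0``.  Each entry is the joint Poisson
    log-likelihood of the pair relative to the saturated model, hence <= 0,
    with equality iff the model rates reproduce both samples exactly.
    """
    for name, arr in (("c", c), ("u", u), ("v_x", v_x), ("v_y", v_y)):
        _check_positive(name, arr)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)

    cu = c[:, None] * u  # (m, n_y)
    # X-side: sum_i X_ik log(c u) decomposes into a matmul plus column sums
    cross = X.T @ np.log(cu)  # (n_x, n_y)
    x_colsum = X.sum(axis=0)  # (n_x,)
    rate_x = np.outer(v_x, cu.sum(axis=0))  # sum_i c u v_xk -> (n_x, n_y)
    x_part = cross + np.outer(x_colsum * np.log(v_x), np.ones(u.shape[1])) - rate_x
    # Y-side and saturated terms are per-column / per-row constants
    y_part = (xlogy(Y, u * v_y[None, :]) - u * v_y[None, :]).sum(axis=0)  # (n_y,)
    sat_x = (xlogy(X, X) - X).sum(axis=0)  # (n_x,)
    sat_y = (xlogy(Y, Y) - Y).sum(axis=0)  # (n_y,)
    return x_part + y_part[None, :] - sat_x[:, None] - sat_y[None, :]


def match_energy(target: CountMatrix, source: CountMatrix, model: PoibmModel) -> np.ndarray:
    """Pairwise match energies for aligned count matrices under a model."""
    return poisson_pair_energy(
        target.counts, source.counts, model.c, model.u, model.v_x, model.v_y
    )


def _newton_polish(
    sub: np.ndarray, f: np.ndarray, g: np.ndarray, r: float, tol: float,
    max_newton: int = 60,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton iterations on the dual of the biproportional scaling problem.

    Minimizes ``D(f, g) = sum exp(sub + f + g) - r sum f - sum g`` whose
    stationary point has row sums r and column sums 1.  The Hessian is the
    arrow-free block matrix [[diag(rows), W], [W^T, diag(cols)]]; a small
    ridge removes the constant-shift gauge direction.
    """
    n_at, n_as = sub.shape

    def dual(fv, gv):
        # overshooting trial steps may overflow to inf; backtracking rejects them
        with np.errstate(over="ignore"):
            return float(np.exp(sub + fv + gv).sum() - r * fv.sum() - gv.sum())

    best = dual(f, g)
    for _ in range(max_newton):
        W = np.exp(sub + f + g)
        rows = W.sum(axis=1)
        cols = W.sum(axis=0)
        if np.abs(rows - r).max() < tol * r and np.abs(cols - 1.0).max() < tol:
            break
        grad = np.concatenate([rows - r, cols - 1.0])
        H = np.zeros((n_at + n_as, n_at + n_as))
        H[:n_at, :n_at] = np.diag(rows)
        H[n_at:, n_at:] = np.diag(cols)
        H[:n_at, n_at:] = W
        H[n_at:, :n_at] = W.T
        H[np.diag_indices_from(H)] += 1e-12 * max(rows.max(), 1.0)
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(40):  # backtracking: the dual is strictly convex
            f_try = f + scale * step[:n_at, None]
            g_try = g + scale * step[None, n_at:]
            val = dual(f_try, g_try)
            if val < best:
                f, g, best = f_try, g_try, val
                break
            scale *= 0.5
        else:
            break
    return f, g


def normalize_weights(
    energy: np.ndarray,
    active_targets: np.ndarray | None = None,
    active_sources: np.ndarray | None = None,
    max_sweeps: int = _SINKHORN_MAX_SWEEPS,
    tol: float = _SINKHORN_TOL,
) -> WeightMatrix:
    """Turn log energies into balanced matching weights.

    Exponentiation is stabilized by subtracting the per-column maximum over
    active rows.  Alternating biproportional rescaling then enforces the
    marginal convexity conditions: each active source column sums to 1 and
    each active target row sums to ``n_active_sources / n_active_targets``.
    Inactive rows and columns are exactly zero.
    """
    energy = np.asarray(energy, dtype=float)
    n_x, n_y = energy.shape
    at = np.ones(n_x, bool) if active_targets is None else np.asarray(active_targets, bool)
    asrc = np.ones(n_y, bool) if active_sources is None else np.asarray(active_sources, bool)
    if not at.any() or not asrc.any():
        raise ValueError("trimming left no active samples on one side")

    sub = energy[np.ix_(at, asrc)]
    if np.any(np.isnan(sub)):
        raise ValueError("energy contains NaN on active entries")
    col_max = sub.max(axis=0)
    if np.any(np.isneginf(col_max)):
        j = int(np.flatnonzero(asrc)[np.argmax(np.isneginf(col_max))])
        raise ValueError(f"source sample {j} has no feasible match (all energies -inf)")

    # log-domain biproportional fitting: deep-count energies span thousands
    # of log units, so linear-space scaling would underflow whole rows
    sub = sub - col_max[None, :]
    n_at, n_as = sub.shape
    log_row_target = np.log(n_as / n_at)

    def lse(mat: np.ndarray, axis: int) -> np.ndarray:
        mx = mat.max(axis=axis, keepdims=True)
        return mx + np.log(np.exp(mat - mx).sum(axis=axis, keepdims=True))

    r = n_as / n_at
    f = np.zeros((n_at, 1))  # row (target) potentials
    g = -lse(sub, axis=0)  # column potentials: columns -> 1
    converged = False
    for _ in range(min(max_sweeps, 200)):
        f = log_row_target - lse(sub + g, axis=1)
        g = -lse(sub + f, axis=0)
        row_sums = np.exp(sub + f + g).sum(axis=1)
        if np.abs(row_sums - r).max() < tol * r:
            converged = True
            break
    if not converged:
        # near-degenerate kernels make alternating scaling crawl; polish with
        # damped Newton on the strictly convex dual of the scaling problem
        f, g = _newton_polish(sub, f, g, r, tol)
    w = np.exp(sub + f + g)
    w = w / w.sum(axis=0, keepdims=True)  # finish on exact column convexity

    full = np.zeros((n_x, n_y))
    full[np.ix_(at, asrc)] = w
    return WeightMatrix(w=full, active_targets=at, active_sources=asrc)


def trim_weights(
    energy: np.ndarray,
    rho_x: float,
    rho_y: float,
    active_targets: np.ndarray | None = None,
    active_sources: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Select the active sample sets for trimming fractions rho_x, rho_y.

    Keeps the ``ceil(rho_x * n_x)`` target and ``ceil(rho_y * n_y)`` source
    samples with the best (maximum) energy over the currently active
    counterpart set (all samples when no mask is given).  Ties are broken
    by sample index for determinism.  With rho = 1 everything stays active.
    """
    energy = np.asarray(energy, dtype=float)
    n_x, n_y = energy.shape
    prev_at = np.ones(n_x, bool) if active_targets is None else np.asarray(active_targets, bool)
    prev_as = np.ones(n_y, bool) if active_sources is None else np.asarray(active_sources, bool)

    n_keep_x = math.ceil(rho_x * n_x)
    n_keep_y = math.ceil(rho_y * n_y)
    if n_keep_x < 1 or n_keep_y < 1:
        raise ValueError("trimming would empty one side")

    def best_k(scores: np.ndarray, n_keep: int) -> np.ndarray:
        # stable sort on (-score, index): lower index wins ties
        order = np.lexsort((np.arange(scores.size), -scores))
        mask = np.zeros(scores.size, bool)
        mask[order[:n_keep]] = True
        return mask

    tgt_scores = energy[:, prev_as].max(axis=1)
    src_scores = energy[prev_at, :].max(axis=0)
    return best_k(tgt_scores, n_keep_x), best_k(src_scores, n_keep_y)


def effective_targets(weights: WeightMatrix, j: int) -> float:
    """Perplexity of source sample j's matching distribution.

    Returns ``exp(H)`` with ``H = -sum_k p_k log p_k`` of the column's
    normalized weights, in units of "target samples": 1 for a one-to-one
    match, the number of active targets for a uniform match.  Inactive
    (trimmed) columns yield NaN.
    """
    if not weights.active_sources[j]:
        return float("nan")
    col = weights.w[:, j]
    total = col.sum()
    if total <= 0:
        return float("nan")
    p = col / total
    return float(np.exp(-xlogy(p, p).sum()))
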