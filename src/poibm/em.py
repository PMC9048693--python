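"""Multistage EM optimization of the sample-matching batch model.

The model couples a target batch X (m genes x n_x samples) and a source
batch Y (m x n_y) through latent matching weights w:

    X_ik ~ Poisson(c_i u_ij v_xk)   with probability w_kj
    Y_ij ~ Poisson(u_ij v_yj)

Each EM iteration updates the weights (energy -> trimming -> balanced
normalization) and then performs coordinate ascent on the parameters
u, v_x, v_y, c in closed form.  Every parameter update is the exact
maximizer of the expected complete-data log-likelihood in its block, so
with no trimming the objective is non-decreasing.  Random restarts (which
randomize the initial trimmed sets) combat local optima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .core import PARAM_FLOOR, CountMatrix, FitConfig, PoibmModel, validate_pair
from .matching import WeightMatrix, normalize_weights, poisson_pair_energy, trim_weights

__all__ = [
    "EmState",
    "init_state",
    "update_u",
    "update_vx",
    "update_vy",
    "update_c",
    "objective",
    "diagnostic_weights",
    "fit",
    "fit_pair",
    "fit_multi",
]

logger = logging.getLogger(__name__)


@dataclass
class EmState:
    model: PoibmModel
    weights: WeightMatrix
    objective_trace: list = field(default_factory=list)
    restart_index: int = 0


def _column_normalized(w: np.ndarray, active_sources: np.ndarray) -> np.ndarray:
    wbar = np.zeros_like(w)
    cols = np.flatnonzero(active_sources)
    sums = w[:, cols].sum(axis=0)
    if np.any(sums <= 0):
        raise ValueError("active source column with zero weight mass")
    wbar[:, cols] = w[:, cols] / sums[None, :]
    return wbar


def init_state(
    target: CountMatrix,
    source: CountMatrix,
    config: FitConfig,
    restart: int = 0,
) -> EmState:
    """Initial EM state: c = 1, v proportional to library sizes (mean 1),
    u from the u-update under uniform weights over the initial active
    targets.  When trimming is on, the initial active sets are drawn
    uniformly at random from a stream derived from (seed, restart)."""
    X, Y = target.counts, source.counts
    m, n_x = X.shape
    n_y = Y.shape[1]
    x_colsum = X.sum(axis=0)
    y_colsum = Y.sum(axis=0)
    if np.any(x_colsum <= 0) or np.any(y_colsum <= 0):
        raise ValueError("a sample has zero total counts; remove degenerate samples first")

    c = np.ones(m)
    v_x = x_colsum / x_colsum.mean()
    v_y = y_colsum / y_colsum.mean()

    import math

    n_keep_x = math.ceil(config.rho_x * n_x)
    n_keep_y = math.ceil(config.rho_y * n_y)
    if n_keep_x == n_x and n_keep_y == n_y:
        at = np.ones(n_x, bool)
        asrc = np.ones(n_y, bool)
    else:
        root = 0 if config.seed is None else int(config.seed)
        rng = np.random.default_rng([root & 0x7FFFFFFF, restart])
        at = np.zeros(n_x, bool)
        at[rng.choice(n_x, size=n_keep_x, replace=False)] = True
        asrc = np.zeros(n_y, bool)
        asrc[rng.choice(n_y, size=n_keep_y, replace=False)] = True

    w = np.zeros((n_x, n_y))
    w[np.ix_(at, np.ones(n_y, bool))] = 1.0 / at.sum()  # uniform over active targets
    weights = WeightMatrix(w=w, active_targets=at, active_sources=asrc)
    u = update_u(X, Y, c, v_x, v_y, w, active_sources=np.ones(n_y, bool))

    model = PoibmModel(
        c=c, u=u, v_x=v_x, v_y=v_y, w=w,
        active_targets=at, active_sources=asrc,
        objective=-np.inf, n_iter=0, converged=False,
        gene_ids=target.gene_ids,
    )
    return EmState(model=model, weights=weights, restart_index=restart)


def update_u(
    X: np.ndarray,
    Y: np.ndarray,
    c: np.ndarray,
    v_x: np.ndarray,
    v_y: np.ndarray,
    w: np.ndarray,
    active_sources: np.ndarray,
    u_prev: np.ndarray | None = None,
) -> np.ndarray:
    """Shared-profile update.

    ``u_ij = (sum_k wbar_kj X_ik + Y_ij) / (c_i sum_k wbar_kj v_xk + v_yj)``
    with column-normalized weights; the virtual target for source j is the
    weighted combination of the target samples.  Only active source columns
    are recomputed; others carry their previous values.  Zero numerators
    are floored at a small positive value to keep logarithms finite.
    """
    wbar = _column_normalized(w, active_sources)
    cols = np.flatnonzero(active_sources)
    num = X @ wbar[:, cols] + Y[:, cols]
    den = c[:, None] * (v_x @ wbar[:, cols])[None, :] + v_y[cols][None, :]
    u_new = np.maximum(num / den, PARAM_FLOOR)
    if u_prev is None:
        u = np.empty((X.shape[0], Y.shape[1]))
        u[:] = np.nan
    else:
        u = u_prev.copy()
    u[:, cols] = u_new
    if np.any(np.isnan(u)):
        raise ValueError("inactive source columns have no previous u to carry over")
    return u


def update_vx(
    X: np.ndarray,
    c: np.ndarray,
    u: np.ndarray,
    w: np.ndarray,
    active_targets: np.ndarray,
    active_sources: np.ndarray,
    v_x_prev: np.ndarray,
) -> np.ndarray:
    """Target total-RNA update: ``v_xk = (sum_i X_ik) / (sum_j what_kj sum_i c_i u_ij)``
    with row-normalized weights over active sources; trimmed targets keep
    their previous value."""
    rows = np.flatnonzero(active_targets)
    cols = np.flatnonzero(active_sources)
    w_sub = w[np.ix_(rows, cols)]
    row_sums = w_sub.sum(axis=1)
    if np.any(row_sums <= 0):
        raise ValueError("active target with zero weight row mass")
    what = w_sub / row_sums[:, None]
    s_cu = (c[:, None] * u[:, cols]).sum(axis=0)  # sum_i c u per active source
    x_colsum = X.sum(axis=0)[rows]
    if np.any(x_colsum <= 0):
        raise ValueError("degenerate target sample with zero total counts")
    v_x = v_x_prev.copy()
    v_x[rows] = x_colsum / (what @ s_cu)
    return v_x


def update_vy(
    Y: np.ndarray,
    u: np.ndarray,
    active_sources: np.ndarray,
    v_y_prev: np.ndarray,
) -> np.ndarray:
    """Source total-RNA update: ``v_yj = (sum_i Y_ij) / (sum_i u_ij)``."""
    cols = np.flatnonzero(active_sources)
    v_y = v_y_prev.copy()
    v_y[cols] = Y[:, cols].sum(axis=0) / u[:, cols].sum(axis=0)
    return np.maximum(v_y, PARAM_FLOOR)


def update_c(
    X: np.ndarray,
    u: np.ndarray,
    v_x: np.ndarray,
    w: np.ndarray,
    active_sources: np.ndarray,
) -> np.ndarray:
    """Batch-coefficient update:
    ``c_i = (sum_kj w_kj X_ik) / (sum_kj w_kj u_ij v_xk)``.
    Genes with zero numerator are floored at a small positive value."""
    wbar = _column_normalized(w, active_sources)
    cols = np.flatnonzero(active_sources)
    num = X @ wbar[:, cols].sum(axis=1)
    t = v_x @ wbar[:, cols]  # sum_k w v_xk per active source
    den = u[:, cols] @ t
    return np.maximum(num / den, PARAM_FLOOR)


def objective(energy: np.ndarray, weights: WeightMatrix) -> float:
    """EM objective: weighted sum of pair energies plus matching entropy.

    ``sum_j sum_k wbar_kj l_kj + sum_j H(wbar_.j)`` over active pairs; the
    weight update is the exact maximizer of this quantity under the
    marginal constraints, the parameter updates increase it for fixed
    weights."""
    rows = weights.active_targets
    cols = weights.active_sources
    wbar = _column_normalized(weights.w, cols)[np.ix_(rows, np.flatnonzero(cols))]
    e = energy[np.ix_(rows, np.flatnonzero(cols))]
    return float((wbar * e).sum() - xlogy(wbar, wbar).sum())


def _run_restart(
    target: CountMatrix,
    source: CountMatrix,
    config: FitConfig,
    restart: int,
) -> EmState:
    X, Y = target.counts, source.counts
    state = init_state(target, source, config, restart)
    model = state.model
    at, asrc = model.active_targets, model.active_sources
    weights = state.weights
    prev_obj = -np.inf
    trimming = config.rho_x < 1.0 or config.rho_y < 1.0

    for it in range(config.max_iter):
        energy = poisson_pair_energy(X, Y, model.c, model.u, model.v_x, model.v_y)
        if trimming:
            # rank over the full counterpart set: ranking only within the
            # current active set can deadlock a true pair out (each member
            # scores poorly while the other is inactive)
            at, asrc = trim_weights(energy, config.rho_x, config.rho_y)
        weights = normalize_weights(energy, at, asrc)
        model.u = update_u(X, Y, model.c, model.v_x, model.v_y, weights.w, asrc, model.u)
        if trimming and not asrc.all():
            # keep trimmed sources' virtual-target profiles fresh (balanced
            # weights over the full population) so their energies stay
            # comparable and a wrongly excluded sample can re-enter; these
            # columns never feed the likelihood or the c/v updates
            full = normalize_weights(energy)
            u_all = update_u(
                X, Y, model.c, model.v_x, model.v_y, full.w,
                np.ones(Y.shape[1], bool), model.u,
            )
            model.u[:, ~asrc] = u_all[:, ~asrc]
        model.v_x = update_vx(X, model.c, model.u, weights.w, at, asrc, model.v_x)
        model.v_y = update_vy(Y, model.u, asrc, model.v_y)
        model.c = update_c(X, model.u, model.v_x, weights.w, asrc)

        energy = poisson_pair_energy(X, Y, model.c, model.u, model.v_x, model.v_y)
        obj = objective(energy, weights)
        state.objective_trace.append(obj)
        logger.debug(
            "restart %d iter %d objective %.6g active %d/%d",
            restart, it, obj, at.sum(), asrc.sum(),
        )
        model.n_iter = it + 1
        if np.isfinite(prev_obj):
            denom = max(abs(prev_obj), 1.0)
            if abs(obj - prev_obj) / denom < config.tol:
                model.converged = True
                prev_obj = obj
                break
        prev_obj = obj

    model.objective = prev_obj
    model.w = weights.w
    model.active_targets = at
    model.active_sources = asrc
    state.weights = weights
    return state


def diagnostic_weights(model: PoibmModel) -> WeightMatrix:
    """Full-population matching diagnostic for a fitted model.

    Active source samples keep their fitted balanced weights; trimmed-out
    sources, which the likelihood never constrained, retain their uniform
    assignment over the active targets — they are mapped uniformly to the
    target population, as expected for samples without a counterpart.
    All sources are marked active so perplexity is defined everywhere.
    """
    w = model.w.copy()
    inactive = ~model.active_sources
    if inactive.any():
        n_at = int(model.active_targets.sum())
        w[:, inactive] = 0.0
        w[np.ix_(model.active_targets, inactive)] = 1.0 / n_at
    return WeightMatrix(
        w=w,
        active_targets=model.active_targets,
        active_sources=np.ones_like(model.active_sources),
    )


def fit(target: CountMatrix, source: CountMatrix, config: FitConfig | None = None) -> PoibmModel:
    """Fit the batch model on a pair of gene-aligned count matrices.

    Runs the configured number of random restarts and returns the model of
    the restart with the highest final objective (ties broken by restart
    index).  With no trimming the initialization is deterministic, so a
    single restart suffices and the rest are skipped.  Deterministic given
    ``config.seed``.
    """
    config = config or FitConfig()
    if not np.array_equal(target.gene_ids, source.gene_ids):
        raise ValueError("matrices are not gene-aligned; run validate_pair first")

    n_restarts = config.n_restarts
    if config.rho_x >= 1.0 and config.rho_y >= 1.0:
        n_restarts = 1  # deterministic init: restarts would be identical

    best: EmState | None = None
    for r in range(n_restarts):
        state = _run_restart(target, source, config, r)
        if not np.isfinite(state.model.objective):
            continue
        if best is None or state.model.objective > best.model.objective:
            best = state
    if best is None:
        raise RuntimeError("all restarts failed to produce a finite objective")
    best.model.validate()
    return best.model


def fit_pair(
    target: CountMatrix, source: CountMatrix, config: FitConfig | None = None
):
    """Validate, align and fit a raw (unaligned) pair of count matrices.

    Returns ``(model, report)`` where the report lists genes dropped during
    alignment; those genes receive a no-op coefficient of 1 when building
    the full correction table (see :mod:`poibm.correct`).
    """
    aligned_target, aligned_source, report = validate_pair(target, source)
    model = fit(aligned_target, aligned_source, config)
    return model, report


def fit_multi(
    batches: dict[str, CountMatrix],
    target: str | None = None,
    config: FitConfig | None = None,
) -> dict[str, PoibmModel]:
    """Fit every non-target batch pairwise against a common target batch.

    The target defaults to the batch with the most samples, the standard
    choice of target space for multi-batch harmonization.
    """
    if len(batches) < 2:
        raise ValueError("need at least two batches")
    if target is None:
        target = max(batches, key=lambda k: batches[k].n_samples)
    if target not in batches:
        raise KeyError(f"unknown target batch {target!r}")
    models = {}
    for label, mat in batches.items():
        if label == target:
            continue
        model, _ = fit_pair(batches[target], mat, config)
        models[label] = model
    return models
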