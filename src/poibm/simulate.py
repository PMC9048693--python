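"""Synthetic multi-batch RNA-seq count data with known ground truth.

Counts are drawn from the generative model the correction assumes:

    count_ij ~ Poisson(a_bi * u_ij * v_j)

where ``a_bi`` are gene-wise batch affinities (log-normal; the reference
batch has a = 1, so the true source-to-target coefficient between batches
t and s is ``a_t / a_s``), ``u_ij`` is the biological expression profile
(log-normal baseline, phenotype fold-changes on a configured gene subset,
optional per-sample biological variability) and ``v_j`` is the per-sample
library size (log-normal around a mean depth).  Profiles are normalized to
sum to 1 per sample so ``v_j`` is directly the expected library size.

An optional gamma multiplier on the rates produces scaled-Poisson
overdispersion; the default is pure Poisson sampling, which is what the
fitting model assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CountMatrix

__all__ = [
    "Phenotype",
    "SimConfig",
    "SimTruth",
    "ReplicateTruth",
    "simulate_batches",
    "simulate_replicates",
]

_MAX_RATE = 1e15


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Log-normal draws with mean 1 and the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


@dataclass(frozen=True)
class Phenotype:
    """A subpopulation: sample counts per batch and its expression signature.

    ``n_affected_genes`` genes (drawn at random) carry log2 fold-changes
    with standard deviation ``effect_log2_sd`` relative to the baseline.
    """

    label: str
    n_per_batch: tuple
    n_affected_genes: int = 0
    effect_log2_sd: float = 1.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults describe a two-batch recovery experiment: 2000 genes, 20
    samples per batch of a single shared phenotype, gene-wise batch
    fold-changes with a log2 standard deviation of 0.25, a mean library
    size of one million reads with 30% between-sample variation, and pure
    Poisson sampling.
    """

    m: int = 2000
    n_batches: int = 2
    phenotypes: tuple = ()
    batch_effect_sd: float = 0.25
    depth: float = 1e6
    depth_cv: float = 0.3
    bio_cv: float = 0.0
    baseline_log2_sd: float = 2.0
    gamma_dispersion: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m < 1 or self.n_batches < 1:
            raise ValueError("m and n_batches must be positive")
        for name in ("batch_effect_sd", "depth_cv", "bio_cv", "gamma_dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        phenos = self.phenotypes or (Phenotype("base", (20,) * self.n_batches),)
        for p in phenos:
            if len(p.n_per_batch) != self.n_batches:
                raise ValueError(f"phenotype {p.label!r} needs counts for every batch")
        object.__setattr__(self, "phenotypes", tuple(phenos))


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated matrices."""

    g: np.ndarray  # baseline profile, sums to 1
    batch_affinity: np.ndarray  # (n_batches, m); reference batch = 1
    fold_changes: dict  # phenotype label -> per-gene fold vector
    v_true: list = field(default_factory=list)  # per batch: per-sample library sizes
    phenotype_labels: list = field(default_factory=list)  # per batch: label per sample
    profiles: list = field(default_factory=list)  # per batch: (m, n_b) sample profiles

    def pair_coefficients(self, target_batch: int, source_batch: int) -> np.ndarray:
        """True gene-wise source-to-target coefficients ``a_t / a_s``."""
        return self.batch_affinity[target_batch] / self.batch_affinity[source_batch]


def _draw_counts(rng: np.random.Generator, rate: np.ndarray, dispersion: float) -> np.ndarray:
    if np.any(rate > _MAX_RATE):
        raise OverflowError("Poisson rate overflow; reduce depth or effect sizes")
    if dispersion > 0:
        shape = 1.0 / dispersion
        rate = rate * rng.gamma(shape=shape, scale=dispersion, size=rate.shape)
    return rng.poisson(rate).astype(float)


def simulate_batches(config: SimConfig) -> tuple[list, SimTruth]:
    """Draw count matrices for every batch plus the full ground truth.

    Deterministic given ``config.seed``.  Returns ``(matrices, truth)``
    with one :class:`~poibm.core.CountMatrix` per batch.
    """
    rng = np.random.default_rng(config.seed)
    m = config.m

    g = 2.0 ** rng.normal(0.0, config.baseline_log2_sd, size=m)
    g = g / g.sum()

    affinity = np.ones((config.n_batches, m))
    for b in range(1, config.n_batches):
        affinity[b] = 2.0 ** rng.normal(0.0, config.batch_effect_sd, size=m)

    folds = {}
    for p in config.phenotypes:
        fold = np.ones(m)
        if p.n_affected_genes > 0:
            idx = rng.choice(m, size=min(p.n_affected_genes, m), replace=False)
            fold[idx] = 2.0 ** rng.normal(0.0, p.effect_log2_sd, size=idx.size)
        folds[p.label] = fold

    matrices = []
    truth = SimTruth(g=g, batch_affinity=affinity, fold_changes=folds)
    for b in range(config.n_batches):
        labels = []
        for p in config.phenotypes:
            labels.extend([p.label] * int(p.n_per_batch[b]))
        n_b = len(labels)
        if n_b == 0:
            raise ValueError(f"batch {b} has no samples")
        profile = np.empty((m, n_b))
        for j, lab in enumerate(labels):
            col = g * folds[lab] * _lognormal_unit_mean(rng, config.bio_cv, m)
            profile[:, j] = col / col.sum()
        v = config.depth * _lognormal_unit_mean(rng, config.depth_cv, n_b)
        rate = affinity[b][:, None] * profile * v[None, :]
        counts = _draw_counts(rng, rate, config.gamma_dispersion)
        sample_ids = np.array([f"b{b}_s{j}_{lab}" for j, lab in enumerate(labels)], dtype=object)
        gene_ids = np.array([f"g{i}" for i in range(m)], dtype=object)
        matrices.append(CountMatrix(counts, gene_ids, sample_ids))
        truth.v_true.append(v)
        truth.phenotype_labels.append(labels)
        truth.profiles.append(profile)
    return matrices, truth


@dataclass
class ReplicateTruth:
    """Ground truth of the replicate-discovery scenario."""

    pairs: list  # (target index, source index) of true duplicates
    c_true: np.ndarray  # source-to-target coefficients
    target_labels: list
    source_labels: list


def simulate_replicates(
    m: int = 500,
    n_shared: int = 10,
    n_unique_target: int = 10,
    n_unique_source: int = 10,
    batch_effect_sd: float = 0.25,
    depth: float = 1e5,
    depth_cv: float = 0.3,
    bio_cv: float = 0.5,
    case_n_genes: int | None = None,
    case_effect_log2_sd: float = 1.0,
    baseline_log2_sd: float = 2.0,
    seed: int | None = None,
) -> tuple[CountMatrix, CountMatrix, ReplicateTruth]:
    """Two batches sharing duplicated samples, plus batch-unique subpopulations.

    The first ``n_shared`` samples of each batch are duplicates: the same
    individual expression profile measured in both batches with different
    gene affinities and library sizes.  Every sample (duplicated or not)
    carries per-sample biological variability ``bio_cv`` around its
    subpopulation profile — each individual is unique, which is what makes
    specific duplicate pairs identifiable.  The remaining samples belong
    to batch-unique subpopulations with distinct fold-change signatures
    per batch, mirroring case subpopulations present in only one batch.
    True duplicate pairs are ``(k, k)`` for k < n_shared.
    """
    rng = np.random.default_rng(seed)
    if case_n_genes is None:
        case_n_genes = max(m // 10, 1)

    g = 2.0 ** rng.normal(0.0, baseline_log2_sd, size=m)
    g = g / g.sum()
    c_true = 2.0 ** rng.normal(0.0, batch_effect_sd, size=m)  # target affinity; source = 1

    def case_fold() -> np.ndarray:
        fold = np.ones(m)
        idx = rng.choice(m, size=min(case_n_genes, m), replace=False)
        fold[idx] = 2.0 ** rng.normal(0.0, case_effect_log2_sd, size=idx.size)
        return fold

    fold_tgt, fold_src = case_fold(), case_fold()

    def individual(base: np.ndarray) -> np.ndarray:
        col = base * _lognormal_unit_mean(rng, bio_cv, m)
        return col / col.sum()

    shared = np.column_stack([individual(g) for _ in range(n_shared)])
    uniq_t = np.column_stack([individual(g * fold_tgt) for _ in range(n_unique_target)])
    uniq_s = np.column_stack([individual(g * fold_src) for _ in range(n_unique_source)])

    prof_t = np.hstack([shared, uniq_t])
    prof_s = np.hstack([shared, uniq_s])
    v_t = depth * _lognormal_unit_mean(rng, depth_cv, prof_t.shape[1])
    v_s = depth * _lognormal_unit_mean(rng, depth_cv, prof_s.shape[1])

    X = _draw_counts(rng, c_true[:, None] * prof_t * v_t[None, :], 0.0)
    Y = _draw_counts(rng, prof_s * v_s[None, :], 0.0)

    gene_ids = np.array([f"g{i}" for i in range(m)], dtype=object)
    t_labels = ["shared"] * n_shared + ["case_target"] * n_unique_target
    s_labels = ["shared"] * n_shared + ["case_source"] * n_unique_source
    target = CountMatrix(
        X, gene_ids, np.array([f"t{j}_{l}" for j, l in enumerate(t_labels)], dtype=object)
    )
    source = CountMatrix(
        Y, gene_ids, np.array([f"s{j}_{l}" for j, l in enumerate(s_labels)], dtype=object)
    )
    truth = ReplicateTruth(
        pairs=[(k, k) for k in range(n_shared)],
        c_true=c_true,
        target_labels=t_labels,
        source_labels=s_labels,
    )
    return target, source, truth
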