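# poibm

Batch correction of RNA-seq count matrices through latent sample matching
under a scaled-Poisson model.

## The problem

Expression datasets aggregated across sites, platforms, or processing
pipelines carry systematic technical ("batch") patterns that confound
downstream analysis. Existing correctors (ComBat, ComBat-seq, RUVSeq) need
known phenotype labels or experimental-design factors to stay unbiased —
rarely available for patient cohorts where the phenotypes are the object of
study. This package corrects batch effects **blindly**: it learns, for each
sample of a source batch, a *virtual reference sample* in the target batch,
and infers the correction from those matches alone.

## The model

Counts in a batch follow a scaled-Poisson model
`X_ij ~ Poisson(c_i u_ij v_j)` with gene-wise batch coefficients `c_i`,
batch-free expression profiles `u_ij`, and per-sample total-RNA factors
`v_j`. Across a target batch X and a source batch Y, each source sample j
is probabilistically matched to target samples with weights `w_kj`:

    X_ik ~ Poisson(c_i u_ij v_xk)  with probability w_kj
    Y_ij ~ Poisson(u_ij v_yj)

The weight of pair (k, j) derives from its Poisson log-likelihood against
the saturated model (a negative deviance), balanced so each source column is
a convex combination and target rows carry equal mass. Trimming fractions
`rho_x`, `rho_y` (default 50%) restrict the model to the best-matching
samples so batch-unique subpopulations cannot bias the correction. The model
is optimized by multistage EM — closed-form updates for `c`, `u`, `v` and
an entropy-regularized balanced-transport update for `w` — with random
restarts (default 20, 100 iterations). Correction is then a gene-wise
multiplication `Ŷ_ij = c_i Y_ij`, applicable out-of-sample.

See `docs/methods.md` for the full derivation conventions, numerics, and
design decisions.

## Worked example

Two simulated batches (1000 genes, depth 10⁵) share a control subpopulation;
each also carries a batch-unique case subpopulation, and the source batch is
distorted by gene-wise fold-changes (log2 SD 0.25):

```python
import numpy as np
from poibm import (FitConfig, SimConfig, Phenotype, simulate_batches, fit,
                   table_from_model, apply_correction, cpm_log, explained_variance)

cfg = SimConfig(
    m=1000, n_batches=2,
    phenotypes=(Phenotype("control", (12, 6)),
                Phenotype("case_a", (5, 0), 100, 1.0),
                Phenotype("case_b", (0, 6), 100, 1.0)),
    batch_effect_sd=0.25, depth=1e5, seed=5)
(target, source), truth = simulate_batches(cfg)

model = fit(target, source, FitConfig(rho_x=0.5, rho_y=0.5, seed=17))
print(f"objective {model.objective:.1f} after {model.n_iter} iterations")

table = table_from_model(model)
corrected = apply_correction(source, table)

c_true = truth.pair_coefficients(0, 1)
print(f"correlation(log c_hat, log c_true) = "
      f"{np.corrcoef(np.log(model.c), np.log(c_true))[0, 1]:.3f}")

condition = np.concatenate(truth.phenotype_labels)
batch = np.array(["b0"] * target.n_samples + ["b1"] * source.n_samples)
for label, counts in (("uncorrected", source.counts), ("corrected", corrected.counts)):
    logdata = cpm_log(np.hstack([target.counts, counts]))
    frac = explained_variance(logdata, batch=batch, condition=condition)
    print(f"{label:11s} mean batch {frac['batch'].mean():.3f} "
          f"condition {frac['condition'].mean():.3f} both {frac['both'].mean():.3f}")
```

Output:

```
objective -3226.0 after 36 iterations
correlation(log c_hat, log c_true) = 0.774
uncorrected mean batch 0.224 condition 0.218 both 0.343
corrected   mean batch 0.052 condition 0.183 both 0.187
```

The fitted coefficients track the simulated truth; after correction the mean
per-gene fraction of variance explained by batch drops from 22% to 5% while
the condition (phenotype) signal is retained — all without the fit ever
seeing the phenotype labels. Among the control samples alone the
batch-explained variance drops more than 20-fold (the residual batch
fraction above is mostly carried by the batch-unique case groups, which by
construction confound batch with biology).

## Command line

```sh
poibm simulate --genes 2000 --samples 20 --seed 1 --out-prefix sim
poibm fit --target sim.batch0.tsv --source sim.batch1.tsv \
          --rho-x 0.5 --rho-y 0.5 --seed 1 --out-prefix fit
poibm apply --coef fit.coefficients.tsv --source new_samples.tsv --out corrected.tsv
poibm eval --matrix fit.corrected.tsv --batch-labels batches.tsv --out-prefix ev
```

`fit` writes the corrected matrix, the per-gene coefficient table, the
sample-matching weight matrix and the total-RNA factors, all as delimited
text with a provenance header.

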