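# divprop

**Propensity-score diversity analysis for multi-site case-control
prediction studies.**

Supervised classifiers trained on clinical neuroimaging cohorts inherit the
demographic make-up of those cohorts: age ranges, sex ratios and scanning
sites all shift both accuracy and the brain patterns a model extracts.
`divprop` quantifies that *cohort diversity* with a single composite index —
the propensity score π = P(Y = 1 | C), the probability of carrying the
diagnosis given the covariates C (age, sex, site) — and measures how
diversity shapes out-of-distribution predictive accuracy and the stability
of the extracted predictive patterns.

## The method in brief

1. **Propensity scores.** A logistic model
   `logit(π) = β₀ + β₁C₁ + … + β_kC_k` fitted on covariates only (never on
   brain features), followed by Platt recalibration so class imbalance does
   not skew the probabilities. Because π is a balancing score, participants
   with similar scores have similar joint covariate profiles.
2. **Matching.** Cases and controls are paired one-to-one by the Hungarian
   algorithm on |π_i − π_j|, subject to a caliper of 0.2 × SD of all
   pairwise absolute score differences. Balance is audited with absolute
   standardized mean differences, `d = |x̄₁ − x̄₀| / √((s₁² + s₀²)/2)`
   (prevalence form for binary covariates); SMD < 0.1 counts as balanced.
3. **Stratification and draws.** Pairs are ranked by pair-mean score and cut
   into q = 10 equally sized strata. Training sets are assembled from r
   strata under *contiguous* (adjacent only), *diverse* (at least one
   isolated stratum, top-ranked by diversity) and *random* schemes, or
   exhaustively (all C(10,5) = 252 splits at r = 5).
4. **Classification.** An L2-penalized logistic model minimizing
   `J(w) = −Σ[y log φ(z) + (1−y) log(1−φ(z))] + λ‖w‖²` with λ tuned by
   inner 5-fold CV over 7 log-spaced points in [1e−3, 1e+3]; features are
   z-scored with training-set statistics only. Within-distribution (WD)
   performance uses 10-fold CV on the training pairs; out-of-distribution
   (OOD) performance is reported per holdout stratum, never pooled.
5. **Diversity indices.** WD diversity `2/(N_t(N_t−1)) Σ_{i<j} |π_i − π_j|`
   within a training set; OOD diversity `1/(N_t N_s) ΣΣ |π_i − π_j|` between
   training set and holdout stratum. Performance is correlated with these
   indices (one point per draw for WD, one per draw × stratum for OOD).
6. **Deconfounding.** Linear residualization of covariates, or two-step
   harmonization: parametric empirical-Bayes removal of per-site additive
   and multiplicative effects (preserving age and sex), then residualization
   of age and sex.
7. **Pattern stability.** Pairwise Pearson consistency of the per-draw
   weight vectors ordered by diversity; per-region one-way ANOVA over five
   diversity groups; threshold-free cluster enhancement (TFCE) with a
   permutation null for family-wise correction; network-level correlations
   between aggregated coefficients and diversity.

A seeded synthetic-cohort generator produces multi-site cohorts with
site-specific demographics, covariate-driven diagnosis assignment, site
batch effects and group effect sizes that vary along the propensity
spectrum, so the entire framework is testable without any data download.

## Worked example

```python
import divprop as dp

pheno, features, truth = dp.generate_toy_single_feature("abide-like", n=1000, seed=0)
config = dp.ExperimentConfig(
    pheno=pheno, features=features, exhaustive=True,
    training=dp.TrainingConfig(lambda_grid=(1.0,), seed=0),
    compute_wd=False, seed=0,
)
result = dp.run_experiment(config)
print(len(result.pairs), "matched pairs,", len(result.draw_results), "draws")
print(dp.performance_diversity_correlations(result)["ood_auc_r"])
```

prints

```
292 matched pairs, 252 draws
-0.710
```

292 case-control pairs survive the caliper; the exhaustive design yields
252 train/holdout splits; and the correlation of −0.71 between OOD
diversity and holdout AUC says that in this scenario — where the group
difference is largest at mid-spectrum propensity scores and fades toward
the extremes — accuracy decays as the holdout stratum moves away from the
training data. The mirror-image scenario (`"hbn-like"`) yields a positive
correlation. The `examples/` directory holds one short script per
capability (matching and balance, OOD prediction, harmonization, pattern
stability); each prints its numbers with a line on what they mean. A thin
CLI (`divprop simulate|propensity|match|stratify|draws|deconfound|run`)
wraps the same functions for shell use.

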