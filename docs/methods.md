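# Methods

This note documents the models and procedures implemented in `divprop`,
the defaults they use, and the choices made where the design was open.

## Propensity model

Diversity is operationalized through the propensity score
π = P(Y = 1 | C): the probability of carrying the diagnosis given age, sex
and scanning site. The estimator is a logistic regression of diagnosis on
the encoded covariates — age z-scored (constants stored so new rows encode
identically), sex as a 0/1 indicator, site as a full one-hot block — with a
very weak ridge penalty (inverse strength C = 1e4) purely for numerical
stability under quasi-separation. Coefficients are never interpreted; only
the fitted probabilities matter, so covariate scaling and collinearity in
the site block are immaterial.

Raw probabilities are passed through a Platt (sigmoid) recalibration so
that class imbalance does not bias them. The calibration map is fitted on
out-of-fold decision scores from 5-fold cross-fitting: fitting it in-sample
would inherit the base model's overconfidence. Final scores are clipped to
[1e−6, 1 − 1e−6] before any logit-scale use downstream.

## Matching

Cases are paired 1:1 with controls by solving the rectangular linear
assignment problem on the cost |π_i − π_j| (`scipy`'s Hungarian solver).
Costs above the caliper are replaced by a forbidden cost of
10 × (max admissible cost + 1) before solving, and any assigned pair above
the caliper is discarded afterwards, so every retained pair satisfies the
constraint. The caliper is 0.2 × d_sd with d_sd the standard deviation of
pairwise absolute score differences over **all participant pairs**
(default); a cross-group variant (case-control pairs only, i.e. exactly the
assignment costs) is available via `MatchingConfig(d_sd_mode="cross")`.
With unequal group sizes, min(n_case, n_control) pairs are assigned before
the discard. Ties are resolved by the solver's deterministic order, and
results are order-stable for sorted inputs.

Balance is audited two ways: absolute standardized mean differences per
covariate (continuous: |x̄₁ − x̄₀| / √((s₁² + s₀²)/2); binary: the
prevalence analogue; SMD < 0.1 flagged as balanced; zero pooled variance
with unequal means reports infinite imbalance), and a covariate-only
logistic classifier whose cross-validated AUC should drop from well above
0.5 before matching to chance after. That audit AUC is computed per fold
and averaged — pooling cross-fold probabilities mixes fold-specific scales
and biases AUC downward. Two caveats worth knowing: optimal matching on an
*estimated* score slightly over-selects case-like controls, and
cross-validated AUC under the null is biased a little below 0.5 at matched
sample sizes, so the post-matching audit typically lands near 0.40-0.50
rather than exactly 0.5.

## Stratification and draw schemes

Matched pairs are ranked by their pair-mean score and split into q = 10
contiguous, equally sized strata; a remainder goes to the lowest-score
strata (configurable), and tied scores break by participant id so the
partition is deterministic.

Training sets of r strata are drawn under three schemes. *Contiguous*
takes every window of adjacent strata (q − r + 1 of them); when fewer than
the requested number of draws exist (default 20), extra draws of the same
training fraction are taken as runs of consecutive pairs in score order,
with starts evenly spaced over the pair list and duplicates removed.
*Diverse* enumerates stratum subsets that contain at least one stratum
isolated from the rest of the training set — the formalization chosen for
"training data composed of noncontiguous strata"; a set like {0,1,3,4,5}
(two abutting blocks, no isolated stratum) does not qualify, while {0,9}
or {0,2,4,6,8} do — ranks them by the WD diversity of the pooled training
scores, and keeps the top draws (ties break lexicographically). *Random*
samples pairs at the same training fraction irrespective of scores, the
conventional CV baseline. The exhaustive mode enumerates all C(q, r)
subsets — 252 at q = 10, r = 5. Matched pairs are the sampling unit in
every scheme, which keeps cases and controls balanced in both train and
holdout by construction.

## Diversity indices

WD diversity of a participant set is the mean absolute pairwise score
difference, computed by a sorted-rank identity in O(n log n); OOD diversity
between a training set and a holdout stratum is the mean absolute
difference over all cross pairs and is symmetric in its arguments. When
only pair summaries are carried forward, each pair contributes its
pair-mean score for both members; within-stratum score spread is small
after matching, so the draw ordering is essentially unchanged.

## Classifier

Diagnosis is predicted from brain features by L2-penalized logistic
regression minimizing J(w) = cross-entropy + λ‖w‖², intercept unpenalized.
The scikit-learn solver parameterizes the objective as
0.5‖w‖² + C·loss, so C = 1/(2λ) exactly maps the documented grid — 7
log-equidistant points in [1e−3, 1e+3] — onto the J(w) parameterization.
λ is selected by inner 5-fold cross-validated AUC (the selection metric is
a package choice; ties go to the smallest grid value). Features are
z-scored with training-row statistics only, and those statistics are
re-applied to evaluation rows; a constant training feature maps to centered
zeros rather than dividing by zero. WD performance is the mean over 10
stratified, seeded outer folds, each running the full fit (z-scoring plus
inner tuning) on its training portion. F1 uses a fixed 0.5 probability
threshold with the diagnosis as the positive class. A single-class
evaluation set leaves AUC undefined (reported missing with a warning); F1
and confusion proportions are still produced. Confusion proportions are
normalized to sum to one and can be broken down by site, sex or any other
grouping, and stratum-level reports can be chunked into 6 diversity-ordered
groups with averaged confusions.

## Deconfounding

*Linear residualization* fits per-feature OLS of the feature on the
confound design (centered columns, implicit intercept) and keeps residuals
re-centered at the grand mean; for a categorical confound this equals
within-level centering. Columns collinear with the intercept (e.g. the last
indicator of a full one-hot block) are dropped with a warning. The stored
column means and coefficients reproduce the transform on new rows, and the
operation is idempotent to 1e−8 relative tolerance.

*Two-step harmonization* first fits the per-feature location-scale
site-effect model: features are standardized with a design of site
indicators plus the preserved covariates (age, sex), per-site additive and
multiplicative effects are shrunk toward parametric empirical-Bayes priors
(normal prior on locations, inverse-gamma on scales, hyperparameters by
moment matching, posterior by the standard fixed-point iteration), and the
shrunken effects are removed. Step 2 residualizes age and sex from the
harmonized data; site is excluded there because step 1 already handled it.
Constant features pass through with a warning; a site with a single
participant is an error. The parametric variant was chosen as the common
default; a nonparametric variant is out of scope. Following the framework's
protocol, deconfounding runs cohort-wide before matching by default; a
leakage-safe mode that refits the deconfounder on each draw's training rows
is available (`deconfound_scope="train"`).

## Pattern stability

The weight vectors of the per-draw model fits form a draws × features
matrix. The consistency matrix is their pairwise Pearson correlation with
rows ordered by ascending WD diversity; it is symmetric with unit diagonal,
invariant to common rescaling, and a zero-variance weight vector yields
missing entries rather than an error. For connectivity features, edge
weights collapse to nodes as the mean over the P − 1 incident edges
(optionally split into positive-only and negative-only means; a node with
no edges of a sign reports missing).

Per-region inference assigns draws to 5 near-equal groups by sorted
diversity and runs a classical one-way ANOVA per region (vectorized; zero
within-group variance with unequal means reports F = ∞, p = 0 without
raising; at 2 groups F equals the two-sample t²). Family-wise correction
uses threshold-free cluster enhancement on the parcel adjacency graph with
E = 0.5, H = 2 and step dh = max(F)/100 — the method's standard defaults —
and a permutation null that shuffles the draws' diversity-group labels
(n_perm = 1000 by default) and records the maximum enhanced statistic;
corrected p = (1 + #{null ≥ observed}) / (n_perm + 1). An empty adjacency
degrades to max-statistic correction with a warning. Because draws share
training pairs they are not independent; the permutation p-values are
calibrated for the null of no group structure given that dependence, an
inferential caveat inherited by any analysis built on overlapping draws.
Network-level analysis averages node values within each named network per
draw (missing values excluded) and correlates the series with diversity.

## Synthetic cohorts

The generator samples per-site demographics (size, sex ratio, truncated
normal age), assigns diagnosis from a logistic model on the covariates —
so the true propensity model lies in the fitted model's family and a
genuine propensity gradient exists — and draws features as
site offset + site scale × (group effect + Gaussian noise), with the group
effect Δx a function of the true score: `a·(1 − |2π − 1|)^γ`
(mid-spectrum effect, "abide-like"), `a·|2π − 1|^γ` (extreme-spectrum
effect, "hbn-like"), constant, or zero. Defaults a = 1.5 (in noise-SD
units) and γ = 1 give a clearly detectable but not trivial signal
(two-Gaussian separation AUC ≈ 0.86 at the peak). All randomness flows
from one seed through named substreams, so a fixed spec reproduces tables
bit-exactly.

Preset compositions mirror the two cohort types the framework targets: a
four-site cohort with a nearly all-male composition and wide age range, and
a three-site cohort whose sex ratio varies strongly across sites (females
concentrated at one site) with site batch effects switched on. A two-site
"confounded null" preset couples all three covariates to the diagnosis
while leaving the features signalless; it exists to audit that matching
removes covariate informativeness. The single-feature toy generator uses
one site with strong age and sex coefficients so estimated scores span most
of (0, 1), and requires n ≥ 80 so ten strata can be filled after matching.

What the generator does *not* emulate: spatial autocorrelation between
parcels, realistic fMRI time-series structure, non-Gaussian feature noise,
and covariate measurement error. Passing tests therefore demonstrate the
framework's internal correctness and calibration, not performance levels on
real cohorts.

## Problem sizes and numerical choices

The toy-scenario experiments use n = 1000 participants, the exhaustive
252-draw design and a single-point λ grid — with one feature the ROC
ranking depends only on the sign of the lone coefficient, which no grid
value flips, so inner CV is vacuous there. Calibration studies use 50 null
replicates with 100 permutations per TFCE run; the balance study uses 20
seeded cohorts of n = 400. These sizes are the package's default study
conditions; all scale up via function arguments. Propensity scores are
clipped at 1e−6; z-scoring floors zero SDs at 1; the EB fixed point stops
at 1e−6 relative change or 200 iterations; matching tolerance in oracle
comparisons is 1e−9.

## Known limitations

- 1:1 matching only; no 1:k, replacement, or exact-covariate matching.
- Strata are equally sized (rank-based), not equal-width in score.
- Inverse-probability weighting and generalized (continuous-target)
  propensity scores are out of scope.
- The diverse scheme's top-k truncation depends on the WD ranking; ties
  beyond the cut are broken lexicographically, which is deterministic but
  arbitrary.
- TFCE parameters (E, H, dh) are method defaults, not tuned to any atlas.
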