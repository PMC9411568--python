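# Methods

## Model

A risk score over genomic features G (CpG beta values for an MRS, allele
dosages for a PRS) is trained jointly with baseline covariates C:

    y = α + G β_G + C β_C + ε ,

with an elastic-net penalty on β_G only,

    λ Σ_j pf_j ( mix·|β_j| + (1−mix)/2 · β_j² ),   pf = 0 on covariates,

so the covariates are fitted at full strength and the genomic block is
shrunk.  The three families fix the mixing parameter: lasso 1, elastic net
0.5, ridge 0.  The link is linear for continuous outcomes and logistic for
binary ones.  Unpenalized covariates are implemented through zero penalty
factors rather than residualization, preserving the joint-fit semantics
under the logistic link (the two are equivalent only for squared error).

Evaluation is 10-fold double cross-validation.  Inside each outer training
fold: genomic and covariate columns are standardized on that fold's
statistics, a lambda path is laid out (log-spaced over four decades down
from the smallest lambda that zeroes every penalized coefficient, 100
values), and an inner 10-fold cross-validation scores each lambda by the
metric of the concatenated inner out-of-fold predictions — AUC for binary
outcomes, squared Pearson R² for continuous ones; the same metric used for
outer evaluation, so selection and evaluation agree.  The winning lambda is
refit on the whole training fold and the held-out fold predicted.  The
concatenated out-of-fold predictor across all folds is the single object all
significance testing consumes.  Binary folds are stratified, which keeps
every fold two-class down to ~5% prevalence.  Fold assignment is seeded per
(master seed, outcome id), so each outcome's pipeline is independently
reproducible.

## Significance framework

Whether an imputation works at all is tested by the univariate regression
y = α + ŷβ + ε (linear or logistic to match the outcome), reporting the
Wald p for β; for the linear link this is computed in closed form (it is
the Pearson correlation t test).  Whether predictor ŷ_j adds signal over
ŷ_i is a 1-df likelihood-ratio test of

    y = α_i + ŷ_i β_i        vs        y = α_ij + ŷ_i β_i + ŷ_j β_j .

For the linear link the statistic is n·log(RSS_reduced/RSS_full).  A ŷ_j
numerically collinear with {1, ŷ_i} is flagged and given p = 1 rather than
a spurious statistic.  Multiple testing is Bonferroni within families
(outcome category × score type), significant iff p < 0.05 / family size.
Metric confidence intervals are percentile bootstrap with B = 1000 paired
resamples; binary resamples that lose a class are redrawn.  Logistic fits
that separate fall back to a ridge-stabilized IRLS (penalty 1e-6).

## Matrix completion

SoftImpute minimizes ½‖P_Ω(X − Z)‖²_F + λ‖Z‖_* by alternating
observed-entry substitution with soft-thresholded SVD.  Columns are
standardized before completion — labs z-scored from their observed entries,
binary columns centered only — so no unit dominates the SVD; observed
entries are restored exactly on output.  The iterate is warm-started down a
geometric path of 10 lambdas from half the top singular value to the target:
cold-starting at a small lambda converges to an arbitrary interpolant of the
observed entries, while the path walk tracks the low-rank solution branch
(this is what makes noiseless low-rank matrices exactly recoverable).  When
no lambda is given, it is selected on a 10% validation split of the observed
entries over that path.  Defaults: rank cap min(n, p, 50), relative
Frobenius tolerance 1e-5, 200 iterations per lambda.

Evaluation mimics clinical ordering: labs arrive in panels, so masking a
target lab's entries for a fold also masks, for the same samples, every lab
sharing a panel with it.  The target's observed entries are split into 10
folds; pooled held-out truths vs imputations give the per-lab R².  The
EHR-only and score-augmented arms see byte-identical masks, and the
improvement is tested by the same nested LRT with the base imputations as
the reduced predictor — chosen for coherence with the rest of the
framework, since "significantly better imputed" does not by itself name a
test.  Score columns are tagged and never masked.

## Synthetic cohorts

The generator produces the structure the analysis assumes, with one RNG
stream per sub-generator split from the master seed (adding variants leaves
methylation draws untouched):

- **Methylation**: per-CpG baselines U(0.05, 0.95), cell-type deviations
  N(0, 0.15) clipped to [0, 1]; sample proportions Dirichlet(5); betas =
  mixture + N(0, 0.02) noise, clipped.  Additive Gaussian noise with
  clipping was chosen over a logit-normal model for transparency; it is
  adequate for noise SD ≤ 0.05, where boundary clipping is negligible.
- **Genotypes**: dosages Binomial(2, p), p uniform on (0.05, 0.45) — exact
  Hardy-Weinberg, no linkage (LD is irrelevant to every property tested
  here).
- **Covariates**: age U(18, 90), sex Bernoulli(1/2), 3-level smoking,
  4-level self-reported group.
- **Outcomes**: sparse effects on 20 standardized CpGs and 10 variants plus
  covariate effects; continuous y adds N(0, 1) noise, binary y is Bernoulli
  through the logistic link with the intercept found by bisection on the
  expected prevalence (and the draw retried with a logit-scale nudge until
  the empirical prevalence lands within ±0.02 — a target finer than the
  1/n granularity raises an explicit error).  When a target oracle R² is
  set (default 0.5) the linear predictor is rescaled so
  var(lp)/(var(lp)+σ²) hits it exactly; binary predictors are scaled
  against the logistic latent variance π²/3 by the same rule.

Default conditions: n = 800 samples, 2000 CpGs, 1000 variants, 5 cell
types, prevalence 0.2.  One property of this generative model deserves
emphasis: because betas are cell-type mixtures, every CpG carries a strong
cell-composition component, so a baseline that includes *estimated cell
proportions* absorbs much of any methylation score's signal — comparisons
against that baseline measure the deconvolution residual rather than the
score.  Model-comparison checks therefore use the demographic covariate
baseline (age, sex, smoking, group), with deconvolution accuracy assessed
separately.  What the generator does **not** emulate: probe-level
intensity artifacts, LD, batch effects, correlated CpG blocks, non-linear
covariate effects, informative (outcome-dependent) lab missingness.
Passing tests therefore certify the statistical machinery — calibration,
leakage-freedom, recovery under the stated generative model — not
performance on real arrays.

## Numerical choices

- **Solver**: glmnet-style coordinate descent with per-feature penalty
  factors, written here because no installed Python library fits
  elastic-net models with unpenalized covariates under both links.  Columns
  are standardized internally (weights reported on the original scale),
  active-set sweeps run in numba with a BLAS gradient screen growing the
  set, and logistic fits use IRLS with probabilities clipped to
  [1e-5, 1−1e-5].  Verified against scikit-learn (gaussian) and R glmnet
  (logistic, exact to ~1e-9 after accounting for glmnet's penalty-factor
  rescaling) and by KKT stationarity checks.  Convergence tolerance 1e-7
  for single fits, 1e-5 along cross-validation paths.
- **Early stopping on the lambda path**: the inner-CV walk stops once the
  metric has not improved by ≥ 0.005 for 10 consecutive lambdas.  The
  minimum-improvement margin matters: the null sampling noise of AUC is
  large enough that chance records would otherwise defeat the stop and
  force the full path on every fold.  Selection still takes the exact
  argmax over evaluated lambdas; on planted-signal checks the selected
  models are identical with patience 10 and patience 30.
- **Ties**: equal CV metrics prefer the sparser family
  (lasso > elastic net > ridge); equal inner metrics prefer the larger
  lambda.  Lab events tied on the most recent date are averaged.
- **Deconvolution**: per-sample min ‖b − Rp‖² s.t. p ≥ 0, Σp = 1, solved
  by SLSQP; a rank-deficient reference warns but still solves.
- **PCA**: genotype PCA standardizes columns, methylation PCA (outlier
  screening) centers only — the convention of each data type.  Component
  signs are fixed by making the largest-magnitude loading positive.  The
  4-SD outlier rule keeps a sample at exactly 4 SD (strict >, with a 1e-12
  relative guard against round-off).
- **QC order**: variant missingness → sample missingness → MAF → HWE →
  chromosome, with per-step removal counts reported, so any discrepancy
  with another ordering is diagnosable.  "More than 1% missing" applies to
  variants and samples both.  HWE uses the 1-df chi-square (monomorphic →
  p = 1): the era-typical convention and closed-form testable.
- **Dates**: "before the collection date" is read strictly, at date
  resolution; events on the collection date are excluded (conservative
  against leakage).  GPI subclass = first 6 characters unless an explicit
  map is supplied.
- **Phecode mapping**: dual-coded (ICD-9 + ICD-10 on the same patient and
  date) records consult only the ICD-10 mapping; unmapped codes drop with a
  logged count.
- **Medication prevalence filter**: applied after subclass grouping.

## Test-suite problem sizes

The suite verifies properties at sizes chosen to make each check decisive
on a single core: oracle equivalence on 100 random instances; null
calibration with 500 replicates at n = 200 and 500 Bonferroni families of
50 tests; leakage-freedom on a pure-noise binary outcome at n = 400 × 2000
CpGs across all three families; planted-signal recovery at the default
cohort (n = 800 × 2000, oracle R² 0.5); completion recovery on rank-2
200 × 30 matrices across 10 seeds; the augmentation comparison over 20
paired-mask replicates; and the learning curve at sizes 150/300/600 with 20
repetitions on a 600 × 500 cohort (10 causal CpGs), the package's chosen
scale for that experiment.

## Known limitations

- The solver targets dense in-memory matrices up to a few thousand
  features; array-scale data (10⁵–10⁶ sites) would need chunked screening
  or summary-level shrinkage, both out of scope.
- Percentile bootstrap intervals can occasionally fail to contain the point
  estimate at extreme metrics; results flag rather than fail.
- The adjusted R² uses the univariate regression degrees of freedom of the
  final association, not the effective degrees of freedom of the penalized
  fit (which is not identifiable from the out-of-fold predictor alone).
- Group labels are taken as given; no ancestry inference is attempted.
- With heavy censoring of the lambda path (patience stops), the selected
  lambda can sit at the path head for null outcomes; this is by design —
  a null outcome has no meaningful lambda.
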