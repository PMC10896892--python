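# Methods

This package implements, end to end, a prognostic polygenic-risk analysis
for coronary artery disease (CAD) cohorts: per-trait pruning-and-thresholding
(P+T) polygenic risk scores built from external GWAS summary statistics,
selection of each trait's optimal P-value threshold against all-cause death,
Cox screening of the optimal scores, their integration into a single
**metaPRS** by cross-validated elastic-net Cox regression, and the
evaluation layer (quartile risk stratification, time-dependent AUCs,
confusion matrices, baseline tables).  Because individual-level cohorts of
this kind are private, the package ships a synthetic cohort generator that
reproduces the statistical structure every stage relies on; all tests and
the acceptance script run against it.

## Quality control

Filters run in a fixed order — sample call rate, variant call rate,
Hardy–Weinberg equilibrium, minor allele frequency, then imputation R² when
present — with strict `<` removal semantics (MAF exactly 0.05 is retained
under the default 5% threshold).  Defaults: call rates 0.95, HWE p 1e-6,
MAF 0.05, imputation R² 0.3.  Imputation R² is consumed as a metadata
column, never computed.

The HWE test is the exact conditional test: given the observed allele
counts, the probability of each heterozygote count is computed (in log
space via `gammaln`, normalised over the admissible parity class) and the
two-sided p-value sums the probabilities of configurations no more likely
than the observed one.  A chi-square approximation would misbehave exactly
where QC needs it (moderate MAF bounds, small expected homozygote counts);
the exact test is also verifiable against brute-force enumeration, which
the test suite does exhaustively for all tables with total ≤ 40 and on a
thousand seeded tables up to 200.

HWE is evaluated on hard calls (dosages rounded to the nearest integer for
this test only), since the test is defined on genotype counts.  Residual
missing dosages are mean-imputed per variant *after* filtering so that
scoring sees a complete matrix; under missingness-at-random this leaves
score expectations unbiased.  A single QC pass is exposed; pipelines that
QC both before and after imputation can simply invoke it twice.

## P+T scores

Allele harmonization aligns each summary-statistics record to the cohort
panel by (chromosome, position): swapped effect/other alleles flip the sign
of beta, strand flips (A↔T, C↔G complements) are resolved, strand-ambiguous
variants (A/T and C/G pairs) are removed by default (switchable — the
convention cannot be recovered from the data itself), and unmatched records
are dropped, all with logged counts.

Clumping is greedy: variants are ordered by ascending p (ties broken by
chromosome, position, id, making output independent of input row order);
the best remaining variant indexes a clump and removes every other
remaining variant within ±250 kb on the same chromosome whose dosage r²
with it exceeds 0.1.  LD is computed on the analysis panel itself, not an
external reference.  Thresholds run log-uniformly from 5e-8 to 0.5
(default 500 steps; the grid is configurable and recorded), and the variant
sets are nested along the grid by construction.

A raw score is the plain weighted dosage sum Σⱼ βⱼ·Gᵢⱼ, without dividing by
allele count; every downstream association uses the z-scored version, so
hazard ratios read "per SD increment" and the normalisation convention
cancels.

## Threshold selection, screening, integration

For each trait and each threshold model, all-cause death is regressed
(logistic, IRLS) on the standardized score plus age, sex, the four
medication indicators (PPI, ACEI, BB, CCB) and 10 genotype PCs; the
threshold maximizing **Nagelkerke R²** — `(1 − exp(2(LL₀−LL₁)/n)) /
(1 − exp(2·LL₀/n))` — wins, ties resolved toward the smaller threshold
(fewer variants).  Covariate adjustment in this step is a deliberate
choice: it keeps the selection target aligned with the Cox screen that
follows (adjustment is switchable).  Identical nested variant sets at
adjacent thresholds are fitted once.  IRLS operates on internally
standardized predictors so convergence (max |score| < 1e-8) and the
separation heuristic (|standardized coefficient| > 15) are invariant to
affine rescaling of the inputs.

Screening keeps traits whose optimal score has Wald p < 0.1 (strict) in a
Cox model with the same adjustment set.  Surviving standardized scores
enter an elastic-net Cox regression:

  minimize  −(1/n)·ℓ(β) + λ·[α‖β‖₁ + ((1−α)/2)‖β‖₂²]

with ℓ the Breslow partial log-likelihood.  The solver is glmnet-style:
an outer quadratic approximation at the current linear predictor
(per-sample gradient and diagonal Hessian), cyclic coordinate descent with
soft-thresholding on the weighted least-squares surrogate, warm starts down
a 100-point log-spaced λ path from λ_max (the smallest λ with an all-zero
solution) to 0.001·λ_max.  Step-halving guarantees the penalized objective
is non-increasing across sweeps, and the objective trace is stored per λ so
the monotonicity contract is testable.  α defaults to 0.5 and is a
required, recorded setting: "elastic net" pins down only 0 < α < 1, and
sensitivity to α should be surfaced rather than hidden.

λ is chosen by 5-fold cross-validation, stratified by event status with a
seeded fold assignment, scoring each fold's out-of-fold linear predictor
with the IPCW AUC (below) at a configurable horizon that defaults to the
cohort's median follow-up; ties prefer the larger λ (sparser model).  The
model is refit on all data at the selected λ.  Trait mixing weights are
then flattened to per-variant weights — weight(j) = Σₜ mixₜ·β_{t,j}/SDₜ,
variants shared across traits summed — so deployment is a single weighted
dosage sum z-scored against the stored training mean/SD; the flattened and
trait-mixing representations give identical sample rankings by
construction.

## Survival machinery

The unpenalized Cox fitter uses Breslow tie handling and Newton–Raphson on
the partial likelihood (convergence |Δℓ| < 1e-9, step halving, Wald SEs
from the inverse observed information).  Breslow rather than Efron keeps
the estimator identical to the brute-force oracle the tests maximize
directly; with the essentially continuous survival times used throughout,
the two differ negligibly.

The time-dependent AUC is the cumulative/dynamic IPCW estimator: cases are
subjects with an observed event by the horizon t, controls those still
under observation past t, pairs weighted by the inverse Kaplan–Meier
estimate of the censoring survival (Ĝ(Tᵢ⁻) for cases, Ĝ(t) for controls —
the latter cancels), marker ties counting ½.  With no censoring before t
it reduces exactly to the empirical cases-vs-controls AUC, which is the
oracle the tests enumerate; it also matches `scikit-survival`'s
`cumulative_dynamic_auc` to ~1e-8 on censored data.  Whether a published
AUC of this kind is computed at a specific horizon or over full follow-up
is often ambiguous; here the horizon is explicit, configurable and
reported.

Kaplan–Meier curves are the plain product-limit estimator; cumulative
incidence is 1 − S(t) (no competing risks — all-cause death is the only
endpoint).

## Evaluation conventions

Risk groups follow the quartile rule: low ≤ Q1, high ≥ Q3, intermediate
strictly between, with Q1/Q3 computed by linear interpolation between order
statistics (the rule is recorded in output because the cutpoints depend on
it).  Group hazard ratios come from a Cox fit on two indicator covariates
with the low group as reference; the per-SD continuous hazard ratio is
reported separately and never conflated with the group-indicator contrasts,
which are a different parameterization.  Confusion matrices predict death
when score > cutoff; the default cutoff maximizes Youden's J on the data at
hand, and published cutoffs can be supplied verbatim.  Display conventions
mirror the field: AUCs to two decimals, sensitivity/specificity to whole
percent.  Baseline tables render mean ± SD or count (percent) by vital
status with a per-variable test plan (pooled t, Mann–Whitney U, or Yates
chi-square); the chi-square uses the continuity correction because that is
what reproduces published baseline-table p-values from their printed
counts, and the uncorrected statistic is available by flag.  The
Mann–Whitney implementation enumerates all assignments exactly when
n₁+n₂ ≤ 12 and otherwise uses the tie-corrected normal approximation
without continuity correction, so identical samples give p = 1 exactly.

## Synthetic cohort generator

The generator supplies the statistical structure the pipeline assumes, not
human genetics per se:

* **Genotypes** follow a Gaussian copula: per LD block, each sample draws
  two independent latent "haplotype" Gaussians with AR(1) correlation
  (default ρ = 0.7) between adjacent variants; thresholding each at the
  allele-frequency quantile (MAF ~ U(0.05, 0.5)) and summing gives the
  dosage.  Haplotype independence puts every variant in exact
  Hardy–Weinberg proportion while adjacent variants are in tunable LD —
  precisely the two properties QC and clumping exercise.  Blocks are
  mutually independent and placed > 250 kb apart, so clumping acts within
  blocks only.  This is deliberately not a coalescent simulation: no
  realistic human LD maps, no demography, no imputation-error model.
* **Trait architecture**: each of the (default 15) traits has 30 causal
  variants; a shared pool of `overlap_fraction × 30` variants with common
  effect sizes enters every trait, making the resulting PRSs correlate the
  way cardiometabolic trait scores do.  Effects are scaled to a target
  heritability (default 0.3).
* **Summary statistics** come from simulated *external* cohorts (default
  n = 10,000) drawn from the same genotype process — mirroring the transfer
  setting in which GWAS weights learned elsewhere are applied to the
  analysis cohort — with per-variant marginal least-squares regression
  giving beta, SE and p.
* **Survival**: log-hazard = Σₜ wₜ·z(true scoreₜ) + covariate effects (age
  0.07/yr, sex 0.3, smoking 0.4 on the log-hazard scale; medication columns
  carried but null by default).  Event times are Weibull (shape 1.3, scale
  28 y; shape 1 recovers the exponential) by inverse transform.  Censoring
  is uniform on (0, h] with h calibrated by bisection so the realized event
  fraction lands within ±1% of the target (default 10%, matching a
  171/1,776 death rate), follow-up capped at 11 years.  An unattainable
  target raises rather than silently under-delivering events.
* **Determinism**: the seed is split (`SeedSequence.spawn`) into
  independent child streams for genotypes, architecture, external GWAS and
  survival, so identical (config, seed) reproduce every artifact
  bit-for-bit, and a held-out cohort can be drawn from the identical
  process under a fresh seed.

Because the generator is this stylised, green tests demonstrate that the
*procedures* are correct and recover planted truth under the stated
assumptions — not that the pipeline's numbers transfer to real cohorts,
where LD structure, ancestry mismatch between GWAS and cohort, and
informative censoring all bite.

## Study-scale choices

The recovery experiments (`metaprs.experiments`) fix: n = 2,000 patients,
nine traits with three causal at 0.35 per SD, disjoint causal sets (so
"null" traits are genuinely null for the screen), 300 variants in 30 LD
blocks, external GWAS n = 8,000, a 20-step threshold grid and a 50-point λ
path.  These are the package's chosen desk-scale study conditions: with 20
causal variants per trait each explains ~1.5% of external phenotype
variance, so GWAS p-values sit near 1e-25 and P+T has honest signal to
find, while one replicate (full pipeline plus held-out evaluation) runs in
a few seconds.  Even with disjoint causal sets, null-trait PRSs pick up
hazard-correlated variants through within-block LD, so the Cox screen
occasionally retains a null trait or two — visible in the multi-seed
retention fractions and expected under the design.

## Numerical conventions

* Missing dosage is NaN, never a numeric sentinel; coordinates are 1-based.
* Dosages are encoded against the file's ALT/effect allele at parse time;
  all re-orientation happens in harmonization, the single place allele
  semantics change.
* Constant dosage vectors have r² = 0 by definition (they cannot be in LD);
  constant candidate scores are skipped with a log entry; constant markers
  evaluate to AUC 0.5 with a degenerate flag.
* λ_max is inflated by 1e-9 relatively so the first path point is exactly
  all-zero despite summation-order rounding.
* Writers emit floats via shortest-round-trip `repr` and readers parse with
  `float_precision="round_trip"`, making every write/read cycle exact and
  CLI outputs byte-reproducible under a fixed seed.
* PCA uses SVD of the standardized dosage matrix (constant columns
  dropped, no LD pruning by default) with a deterministic sign convention:
  the largest-magnitude loading of each component is positive.

## Known limitations

* PLINK `.raw` input carries no coordinates or other allele; such panels
  get chromosome "0", ordinal positions and other-allele "N" (matched on
  effect allele only during harmonization), which disables genuine
  positional clumping.
* The elastic-net CV metric is a single-horizon AUC; no integrated
  (time-averaged) criterion is offered.
* No time-varying covariates, competing risks, stratified Cox, or
  shrinkage/Bayesian PRS weighting (LDpred-style) — the P+T and elastic-net
  machinery is the scope.
* The Cox screen inherits the usual multiplicity caveat of a p < 0.1 filter
  applied per trait; the elastic-net stage, not the screen, is responsible
  for sparsity among the survivors.
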