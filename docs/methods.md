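# Methods

## The generative model

The synthetic cohort emulates a Taiwan-Biobank-like population in which
PCSK9 variation shifts LDL-C and LDL-C mediates the genetic effect on
diabetes (DM).  For sample i with dosages g_ij ∈ {0, 1, 2}:

    log10(LDL_i) = log10(μ) + Σ_j β_j g_ij + Σ_k a_k (c_ik − c̄_k)
                   + c·U_i + ε_i,          ε_i ~ N(0, σ²)
    logit P(DM_i = 1) = b0 + θ·log10(LDL_i) + c_DM·U_i

U is a standard-normal unobserved confounder; covariates c_k (age, sex,
BMI, smoking) enter centred so the marginal LDL-C location stays at μ.
Genotypes are Binomial(2, MAF) draws (Hardy–Weinberg) unless a variant
belongs to an LD block, in which case dosages come from a latent Gaussian
copula (below).  DM status is modelled directly as a Bernoulli draw; the
glucose/HbA1c traits that define clinical DM are not simulated, so the
outcome is "case status under the assumed logistic model", which is
exactly what the estimators assume.

### Default parameters (the study conditions)

| parameter | default | units | rationale |
|---|---|---|---|
| n_samples | 75,441 | — | the analysed cohort size |
| variants | 7 PCSK9 variants | — | published MAF (0.0004–0.3475) and per-allele log10-LDL β (−0.1301…+0.0065) |
| μ (ldl_mean) | 120.9 | mg/dL | published cohort mean LDL-C |
| σ (ldl_log10_sd) | 0.11 | log10 units | lognormal fit of 120.9 ± 31 mg/dL: var = ln(1+CV²)/ln(10)² ≈ 0.012 |
| θ (theta_causal) | −4.2294 | log-odds per log10 LDL-C | the published 7-variant WGRS IV estimate, taken as the structural truth |
| b0 | 6.22 | log-odds | sets DM prevalence ≈ 7% at LDL-C 120.9 |
| c (confounder_strength) | 0.055 | log10 units per SD of U | ≈25% of log10-LDL variance from confounding |
| c_DM | 0.49 | log-odds per SD of U | with c = 0.055, drives the observational slope to ≈ −2.0, the published observational coefficient, while θ = −4.23 |
| covariate effects | age 0.0015/yr, BMI 0.0051/(kg/m²) | log10 units | published stepwise coefficients; sex and smoking 0 (dropped in the published LDL model) |
| missing_rate | 0 | — | missingness is opt-in so QC filters are testable |
| seed | 1 | — | every stochastic operation takes an explicit seed |

**Base of the lipid log-transform.** The trait is log10-transformed.  The
base is pinned by the variance partition: 2·MAF·(1−MAF)·β²/σ² with
σ² ≈ 0.012 (log10 variance of 120.9 ± 31 mg/dL) reproduces the published
per-variant LDL r² for the three rare, LD-free coding variants
(0.0015/0.0011/0.0005 computed vs 0.0014/0.0011/0.0005 published);
the same arithmetic on the natural-log scale misses by a factor ln(10)².
For the common variants the published stepwise increments are LD-shrunk
and not comparable to the independent-variant closed form — the
generator draws variants independently by default, so its stepwise
genetic r² sums to the analytic ≈0.0056 rather than the published
0.0049, and tests assert the analytic value.

**Confounding structure.** With confounder_strength = 0 the observational
and causal effects coincide in expectation; with the defaults only the
instrumented estimate is consistent for θ.  The default loadings were
derived from the published observational/IV contrast (−2.0 vs −4.23)
before any testing, via the linear-projection bias c·c_DM/σ²_total.

### LD blocks: latent Gaussian copula

For a block with target pairwise dosage correlation r, each variant's
dosage is a double-threshold discretisation of a latent standard normal
(thresholds at the HWE genotype quantiles), and the latent correlation is
calibrated by bisection against the exact discretised-dosage correlation
(computed from bivariate-normal rectangle probabilities), so the
realised dosage correlation hits the target rather than the attenuated
value naive thresholding would give.  Targets beyond the attainable
range for the pair of MAFs raise an error.  Multi-variant blocks build
the latent matrix pairwise and project to the nearest PSD correlation
matrix if needed.

### What the generator does and does not emulate

It reproduces: HWE genotype marginals, the published MAF/effect pairs,
a lognormal LDL-C distribution, covariate structure, missingness,
confounding with a tunable strength, direct (pleiotropic)
genotype-to-outcome paths via `spike_pleiotropy`, and block LD on
request.  It does **not** model haplotypes, imputation error, population
structure or relatedness, genotype-environment interaction, or the
clinical phenotype cascade behind DM diagnosis.  Passing tests therefore
demonstrate that the estimators recover the parameters of this
generative class — not that the published point estimates are correct on
the real cohort, whose individual-level data are not deposited.

## Quality control

Filters run in a fixed order: sample call rate ≥ 0.97 → variant call
rate ≥ 0.97 → HWE p ≥ 1e-6 (1-df χ² without continuity correction; an
exact test is available behind a flag) → MAF ≥ 0.01.  The order is a
convention (it changes the per-filter removal counts, which is why it is
fixed and reported); each variant is counted against the first filter it
fails.  Variants named in `keep_rare` are exempt from the MAF filter
only, because rare coding variants are analysed separately on pre-QC
data.  QC is idempotent and the report counts reconcile exactly with the
matrix shapes.

## Association machinery

Linear fits are OLS (orthogonal-decomposition path) with two-sided t
p-values; partial r² of a predictor is (RSS_without − RSS_with)/TSS.
Logistic fits are Newton/IRLS maximum likelihood with Wald (normal)
inference; complete separation or any non-convergence is surfaced as a
flag, never silent estimates.  Scans are per-variant complete-case, so n
varies across variants under missingness (as in the published per-variant
Ns).  Monomorphic variants yield flagged, undefined statistics rather
than errors.  LD is composite r² (squared Pearson correlation of
dosages over pairwise-complete samples; no phasing).  The genome-wide
threshold is 5e-8; the genotype–phenotype Bonferroni threshold is
0.05/33 ≈ 0.0015 for the 33 clinical traits.

## Locus dissection conventions

Conditional rounds add previous leads as covariates; ties on p break by
lower genomic position; a variant collinear with the conditioning set is
skipped with a log entry.  A `max_rounds` guard (10) forces termination.
The instrument-entry threshold for conditional rounds defaults to 1e-6,
separate from the 5e-8 reporting threshold: the exon-12 gain-of-function
variant in the motivating analysis was retained at conditional
p ≈ 2e-7 despite falling short of genome-wide significance, and the
pipeline mirrors that practice while recording each instrument's
selection provenance.  LD pruning is greedy in ascending p (keep best,
drop later variants with r² ≥ 0.3 against a kept one) — the published
analysis states the r² < 0.3 outcome, not the algorithm, so the greedy
convention is documented rather than inferred.  Stepwise selection uses
the conventional 0.05 entry / 0.10 removal thresholds with covariates
always in the model and an oscillation guard at 100 steps.

## MR estimator conventions

- **2SLS with a binary outcome** is predictor substitution (logistic
  second stage on the stage-1 fitted exposure).  Its estimand differs
  subtly from the logistic structural parameter through
  non-collapsibility; at the default ≈7% outcome prevalence the
  attenuation is well inside Monte-Carlo error of the recovery tests.
  The reported SE is the naive stage-2 SE, flagged "uncorrected"; a
  first-stage F below 10 attaches a weak-instrument warning.
- **Wald ratio** SE is first-order delta method including the
  exposure-uncertainty term.
- **IVW** is fixed-effect with first-order weights βx²/se_y² (no NOME
  adjustment); Cochran's Q uses the same weights on m−1 df.  A
  single-instrument IVW is by definition the Wald ratio (with its full
  delta-method SE), so the two agree exactly at m = 1.
- **MR-Egger** is WLS of outcome betas on exposure betas (weights
  1/se_y²) after orienting every instrument to its exposure-raising
  allele; SEs carry the estimated residual dispersion with t inference
  on m−2 df (matching a standard WLS fit, against which it is
  cross-checked).
- **Median estimators** use the cumulative-weight-0.5 linear
  interpolation convention (midpoint cumulative weights); SEs come from
  a seeded parametric bootstrap (default 1,000 draws) resampling both
  beta vectors from their SEs; the seed is recorded in the output.
- **Unit conversions** fix 1 mmol/L = 38.67 mg/dL; a log10-scale slope
  converts to an OR per absolute unit locally at a reference LDL-C level
  (OR = exp(β/(ln10·L)) per mg/dL), since the log scale is nonlinear in
  absolute units.
- All estimators are invariant to simultaneous allele flips and to
  instrument reordering.

## Reproducibility and problem sizes

All randomness descends from a single integer seed; the pipeline derives
per-stage seeds through `SeedSequence([seed, stage_index])`, so a rerun
of the same config is byte-identical and stage-level reruns are stable.
Simulation-based tests use fixed seeds with tolerances stated in
Monte-Carlo standard errors.  Recovery suites run 20 replicates at the
full n = 75,441 where the claim concerns that cohort size (variance
partition, 2SLS consistency) and smaller cohorts (n = 4,000–30,000) with
effects sized for essentially full power where the claim is structural
(selection order, filter behaviour, calibration), keeping the default
suite fast while leaving the full-size behaviour covered.

## Known limitations

- Stage-2 SEs ignore first-stage estimation error (a seeded bootstrap is
  the recommended alternative when the instrument is weak).
- The exclusion-restriction filter conditions on observed LDL-C, so
  collider bias is possible in principle when both confounding and
  direct effects are strong.
- Summary-level estimators assume independent instruments; LD-aware MR
  is out of scope, as are MR-PRESSO, multivariable MR and colocalization.
- VCF support is GT-based biallelic SNVs only (dosage/DS fields, indels
  and BGEN/PLINK-BED are out of scope); malformed records are reported
  at record granularity.
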