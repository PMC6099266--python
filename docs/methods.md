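# Methods

## Causal model and estimand

The analysis treats circulating 25-hydroxyvitamin D (25OHD) as a modifiable
exposure whose causal effect on oral and oropharyngeal cancer risk is
identified through genetic instruments. Five SNPs with replicated
genome-wide-significant associations to 25OHD serve as the instrument;
their per-allele effects `β_j` (with standard errors `SE_j`) are expressed
per SD of log 25OHD, taken from an external European-ancestry GWAS, so the
design is two-sample: weights from the exposure GWAS, genotypes and
outcomes from the cancer case-control collection.

The per-individual score `s_i = Σ_j β_j g_ij` ("relative 25OHD") is used
directly as the exposure proxy in a logistic regression of case status on
`s` plus covariates. The score coefficient `θ` is the causal log odds
ratio per SD increase in log 25OHD. The score is *not* divided by `Σβ_j`
or re-standardized within the cohort: each `β_j` is already on the per-SD
scale, and rescaling would silently change the estimand's units.

Standard MR assumptions apply: the SNPs are associated with 25OHD
(relevance, checked via the instrument R²), independent of confounders of
the exposure-outcome relation (checked empirically by the balance tests),
and affect cancer risk only through 25OHD (no horizontal pleiotropy;
probed by leave-one-out and all-subsets refits). Pairwise independence of
the instrument SNPs (linkage equilibrium) is an input contract, not
something the package verifies from genotypes.

## Harmonization

Cohort dosages are re-oriented to each weight's effect allele before
scoring: identity when alleles match, `2 − d` when effect/other are
swapped, a strand-complement lookup when the cohort reports the opposite
strand, and both together. Palindromic sites (A/T, C/G) cannot be resolved
by allele labels; `harmonize` drops them by default with a warning, while
frequency-based inference (orient so the cohort EAF is nearer the weight
EAF) is available and is the default on the VCF reading path, because the
packaged instrument contains one A/T variant (rs6013897, EAF 0.791, far
enough from 0.5 for frequency inference to be reliable). A warning is
raised when cohort and weight EAF disagree by more than 0.2 after
harmonization.

## Bootstrap correction for weight imprecision

The GWAS weights are estimates; ignoring their sampling error understates
the uncertainty of `θ̂`. The package propagates it with a parametric
bootstrap: replicate weight vectors `β*_jb ~ N(β_j, SE_j)`, drawn
independently across SNPs (no between-SNP covariance is published for the
source GWAS), rebuild the score and refit the model, then

    se_corrected² = se_naive² + Var_b(θ*_b),

with the point estimate kept at the original-weight fit. The
variance-addition form is used because the replicate spread isolates the
weight-uncertainty component; the alternative of reporting the replicate
SD alone is available (`bootstrap_sd_only`). Wald (normal) confidence
intervals are used throughout. Default B = 1,000; replicate fits are
warm-started at the main fit, non-convergent replicates are dropped with a
warning and more than 10% dropped is an error.

## Logistic solver

Fits are Newton-Raphson (IRLS) with step-halving on the log-likelihood,
convergence tolerance 1e-8 on the mean score, at most 100 iterations, and
separation detection (coefficients exceeding ±50 abort with an error
naming the stratum). Standard errors come from the inverse observed
information. The solver lives in the package so that the thousands of
bootstrap and subset refits stay cheap; the test suite verifies it against
`statsmodels.Logit` to 1e-6 on coefficients and standard errors.
Categorical covariates are dummy-coded against their first level;
individuals missing any covariate or (under the default policy) any
instrument dosage are excluded from the fit. The optional alternative
imputes missing dosages at their Hardy-Weinberg expectation `2·EAF`.

## Meta-analysis

Regional (and, at a second level, cross-cohort) estimates are pooled by
DerSimonian–Laird random effects: fixed weights `w_i = 1/se_i²` give
Cochran's `Q`; `τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))`; random-effects
weights `1/(se_i² + τ²)` give the pooled estimate and SE. `I² = max(0,
(Q−(k−1))/Q)` with the Higgins–Thompson test-based interval on `ln H`
(`H = sqrt(Q/(k−1))` floored at 1), truncated to [0, 1]; with k = 2 and
small Q the large-sample SE of `ln H` is undefined and the interval is
reported as [0, 1]. z-based CIs are used for the pooled estimate
(Hartung–Knapp is not implemented), and REML τ² is out of scope —
DerSimonian–Laird matches the conventions of the standard R meta-analysis
packages. `se_from_ci` inverts a printed OR and 95% CI to a log-OR SE
assuming symmetry on the log scale, enabling summary-level pooling of
published results.

## Power

The detectable OR uses the normal approximation for a binary outcome with
an allele-score instrument: `b = (z_{1−α/2} + z_{pow}) / sqrt(N R² φ(1−φ))`
with case fraction φ, reported as `(exp(−b), exp(+b))`; power at a given
OR is the inverse. Defaults α = 0.05, power 0.8. This is the
approximation behind the widely used online MR power calculator; it
reproduces the published detectable-OR bounds for this study design from
the printed inputs, which is the package's validation of the formula
choice.

## The synthetic cohort generator

The simulator's job is to produce data with exactly the statistical
structure the estimator assumes, at the scale of the original collection,
so that calibration claims are meaningful:

* **Genotypes** — `Binomial(2, EAF_j)` per SNP, independent across SNPs
  (Hardy-Weinberg, linkage equilibrium), at the packaged weight EAFs.
* **Exposure** — directly on the standardized log scale:
  `x_i = s_i − E[s] + ε_i`, with `ε` normal and scaled so `Var(x) = 1`;
  the instrument's variance explained then equals the analytic
  `Σ β_j² 2p_j(1−p_j)` ≈ 0.0438. Raw nmol/L units are never modelled.
* **Outcome** — `logit P(case) = α + θ·x + covariate effects`, with the
  intercept solved numerically so the population case fraction equals
  `baseline_case_fraction` (default 0.25; an unreachable target raises an
  error suggesting an adjustment). Sampling is *retrospective*: a
  population pool ~30% larger than required is simulated per stratum and
  the configured numbers of cases and controls are drawn from it, matching
  the case-control design; logistic slopes are consistent under
  outcome-dependent sampling. Cases are labelled oral vs oropharyngeal
  52.6 : 47.4 by default.
* **Strata** — default sizes mirror the three regions of the original
  collection (Europe 2,323/2,928; North America 2,254/2,329; South America
  556/727 cases/controls; 11,117 in total).
* **Covariates** — sex, age band, smoking, alcohol drawn from the
  collection's marginal frequencies including questionnaire missingness;
  their default outcome effects (current smoking log-OR 1.1, ever-alcohol
  0.4, male 0.26, rising age effects) reflect the dominant risk-factor
  structure of these cancers. They are generated independent of genotype,
  so instrument-confounder balance tests have a true null. Principal
  components are standard normal with stratum mean offsets on the leading
  three.
* **Structure scenario** — a hidden subpopulation (default fraction 0.5)
  inside one stratum (default South America) carries shifted allele
  frequencies (stratum-average shifts of 0.01–0.125 per SNP, concentrated
  into the subgroup) and an extra disease log-odds of 1.4. Within that
  stratum the score then correlates with risk through the subgroup even at
  θ = 0, producing a spuriously elevated regional OR and high cross-region
  I² that disappear when the stratum is excluded — a qualitative replica
  of a chance population-structure artifact. The shift magnitudes and
  subgroup effect are illustrative user parameters chosen to make the
  artifact robustly detectable at the default regional sample sizes; no
  numeric regional frequency data exist to calibrate them against.
* **Pleiotropy hook** — `pleiotropy_log_or` adds a direct per-allele
  outcome effect for chosen SNPs, used to validate that leave-one-out
  analysis flags the offending variant.

The generator does **not** emulate linkage disequilibrium between
instrument SNPs, genotyping/imputation error, HPV status, or
ancestry-driven continuous allele-frequency clines (PCs are pure noise
plus stratum offsets, so they cannot absorb the planted structure).
Passing tests therefore demonstrate the estimator's behaviour under the
model's own assumptions — calibration, not robustness to real-data
violations of them.

A deterministic ~2,000-participant fixture (`packaged_fixture`) is
regenerated on demand from a frozen configuration and seed (regional
proportions preserved, 5 PCs) rather than shipped as a file; tests verify
bit-reproducibility.

## Numerical and design choices

* All randomness flows through `numpy.random.default_rng` seeded from
  configuration; same config + seed ⇒ byte-identical cohorts and reports.
* Site analyses share the full control set ("combined" is the union of
  oral and oropharyngeal cases against the same controls), matching the
  original design's shared-control structure.
* Singleton instruments are included in the all-subsets analysis
  (2^k − 1 subsets, guarded at k ≤ 12); leave-one-out rows coincide with
  the (k−1)-sized subsets by construction, which the tests assert.
* Balance p-values are reported raw alongside a Bonferroni column; no
  specific multiplicity procedure is prescribed.
* Meta-analysis of a single estimate returns it unchanged with a warning
  (τ² = 0, I² reported as 0).

## Problem sizes used in the test suite

Calibration tests run at the scale the claims refer to: 50,000 samples
for instrument-strength and Hardy-Weinberg checks; 200 replicates per
causal effect (θ = 0, log 0.8, log 1.3) at the full 11,117-participant
scale with B = 40 bootstrap replicates for bias/coverage; 500 null
replicates for type-I error and balance uniformity; 100 replicates for
the structure-artifact reproduction; 500 replicates for the Monte-Carlo
power check. B = 40 suffices for coverage because the weight-uncertainty
component is a small fraction of the total variance at this instrument
strength; the B-convergence property is tested separately at B = 2,000.

## Known limitations

* No LD-aware instrument handling and no MR-Egger / weighted-median
  estimators; with five SNPs those have little power and are out of scope.
* The bootstrap draws weights independently across SNPs; if the source
  GWAS effects were correlated, the correction would be slightly
  mis-calibrated.
* Logistic non-collapsibility: with unadjusted independent risk factors
  present, the marginal score coefficient is attenuated by a few percent
  relative to the fully conditional effect; at this instrument strength
  the bias is well under the estimator's sampling noise, and the coverage
  tests bound its practical impact.
* Only bi-allelic SNPs and a single-cohort-per-file layout are supported;
  BGEN/PLINK formats are not read.
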