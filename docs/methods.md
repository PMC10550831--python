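# Methods note

This note records the statistical model, the algorithmic choices, the scope
of the synthetic data generator, and known limitations. Every numeric claim
here is computed by the test suite or by `scripts/acceptance.py`; nothing
is asserted from outside sources.

## Variants and phenotype model

Three CYP2C19 index variants are handled (GRCh38, chr10, 1-based):

| star | rsid       | position  | ref>alt | effect           |
|------|------------|-----------|---------|------------------|
| \*2  | rs4244285  | 94781859  | G>A     | loss of function |
| \*3  | rs4986893  | 94780653  | G>A     | loss of function |
| \*17 | rs12248560 | 94761900  | C>T     | gain of function |

Per-sample alternate-allele dosages (0/1/2, −1 for missing) are read from
VCF (GT, falling back to DS when GT is absent) or from a dosage TSV.
Fractional dosages are rounded; values more than 0.1 from an integer are
set missing. Allele-swapped VCF records are flipped with a warning;
multi-allelic records at an index site are an error.

Diplotype calling treats the dosages as unphased counts. With
`lof = d2 + d3`: `lof > 2` is inconsistent (INDETERMINATE); `lof = 2` is
PM; `lof = 1` is IM; otherwise the effective \*17 count is
`min(d17, 2 − lof)` (a \*17 on a LOF haplotype does not rescue function),
giving NM/RM/UM for 0/1/2. Any missing dosage gives INDETERMINATE. The
sensitivity reclassification option moves 1-LOF carriers that also carry
\*17 from IM to NM; an exhaustive test over all 27 dosage triples pins the
full truth table under both settings.

## Statistical methods

- **HWE exact test** (`hwe_exact_test`): conditional on the observed
  allele counts, the heterozygote count has a known exact distribution
  under random mating; the p-value sums the probabilities of all
  heterozygote counts whose conditional probability does not exceed the
  observed one (no mid-p). Probabilities are computed in log space via
  `gammaln`, with a relative tie tolerance of 1e−12. Verified against an
  exact-rational (`fractions.Fraction`) enumeration and, by simulation,
  shown to reject at ~5% under the null and more often under inbreeding.
- **Fisher exact test, two-sided** (`fisher_exact_two_sided`): sum of
  hypergeometric masses ≤ the observed mass (the scipy convention),
  delegated to `scipy.stats.fisher_exact` and verified against an
  exact-rational enumeration for all table totals ≤ 60 at 1e−12. A table
  with an empty margin is reported as degenerate with p = 1.
- **Welch t from summary statistics**: `scipy.stats.ttest_ind_from_stats`
  with unequal variances, checked against the closed form.
- **Logistic regression** (`fit_logistic`): Newton/IRLS with an intercept
  warm start at `logit(mean(y))` and deviance-based step-halving (up to 25
  halvings per iteration). Standard errors are Wald, from the inverse
  observed information; odds-ratio intervals are `exp(β ± 1.96·SE)`.
  Separation is flagged when no deviance-decreasing step exists, a
  coefficient exceeds 15 in absolute value, or the information matrix is
  singular. Verified against Nelder–Mead likelihood maximization (1e−4),
  `statsmodels` GLM (1e−8), and closed-form group log-odds.
- **Collinearity**: per-column variance inflation factors from least-squares
  R²; perfect collinearity reports an infinite VIF with a flag, values
  above 5 are flagged.

The multivariable model regresses recurrent MI on the exposure
(PM/IM/UM indicators with NM+RM as reference, or 0/1/2 LOF-allele dose
with UM always excluded) plus male sex, age in years (uncentered),
diabetes, hypertension, dyslipidemia, obesity, chronic kidney disease,
ever-smoking, PCI, and optionally 20 principal components. Rows with
missing PCI are dropped and counted; drops are recorded on the fit object.

## EHR linkage conventions

Conditions are flagged by ICD-10 prefix match (I21 acute MI, I22
recurrent MI, E10/E11/E13/E14 diabetes, E78 dyslipidemia, E66 obesity,
N18 CKD, I10 hypertension, Z955 PCI) and smoking by SNOMED concept
(77176002/449868002 current, 8517006 ex, 266919005/8392000 never; ever >
never > unknown, unknown coded as never in the analysis table).
Clopidogrel 75 mg is matched by word-prefix on the prescription text. PCI
is missing (not false) for participants without secondary-care coverage.
The cohort flow (participants → with prescribing data → with acute MI →
with clopidogrel 75 mg → analysis rows) is reconciled row-for-row in the
pipeline report.

## Synthetic generator: scope and calibration

The generator emulates a single-timepoint acute-MI clopidogrel cohort. Two
diplotype modes: `class_frequencies` (default class probabilities PM 0.13,
IM 0.44, NM 0.25, RM 0.153, UM 0.027, with within-class \*3 and \*17
composition fractions) and `hwe_haplotype` (haplotype frequencies \*1
0.508, \*2 0.337, \*3 0.006, \*17 0.149, with an optional inbreeding
coefficient F). Binary covariates are independent Bernoulli draws at
configured prevalences (defaults: male 0.80, diabetes 0.71, hypertension
0.91, dyslipidemia 0.90, obesity 0.31, CKD 0.38, ever-smoker 0.90, PCI
0.60); age is normal (61, 12²) truncated at 18. Twenty standard-normal
principal-component columns are included for the PC-adjusted model.

The outcome follows the logistic model with default effects ln(3.12) for
PM, ln(1.47) for IM, ln(10.49) for UM, ln(1.04) per year of age
(categorical mode) or ln(1.95) per LOF allele (dose mode). When the
intercept is unspecified it is calibrated by 80 bisection steps on the
realized linear predictors so the expected marginal event rate equals the
target (default 0.056); the calibration is exact to 1e−6 on the expected
rate. PCI missingness removes secondary-care coverage for a fixed count of
participants (default 14, exactly one of them a case — the "single_case"
pattern; a "random" pattern is also available).

Everything is driven by one `numpy` Generator seeded from the config:
identical config + seed reproduces byte-identical output files.

Verified calibration (test suite / acceptance script): class prevalences
at n = 50,000 within PM 13% ± 1, PM+IM 57% ± 1, UM 2.7% ± 0.5; marginal
event rate 5.6% ± 0.3 percentage points; recovered adjusted odds ratios at
n = 200,000 within 5% of the configured values (PM 3.12, LOF dose 1.95).

## Numerical choices

- Exact tests in log space (`gammaln`) with a 1e−12 relative tie
  tolerance; oracle comparisons use exact rational arithmetic.
- IRLS convergence on the max absolute score with tolerance 1e−8, max 25
  iterations; step-halving guards against overshoot from the cold start.
- Intercept calibration by bisection on [−40, 10], 80 iterations
  (deterministic, derivative-free, monotone objective).
- Problem sizes in the validation suite (n = 697, 50,000, 200,000; 1,000
  replicate cohorts for type-I error) are the package's own choices,
  sized so each check has adequate power while keeping the suite fast.

## Limitations

- Only the three index star alleles are modeled; rarer CYP2C19 alleles
  (\*4–\*35) and structural variants are out of scope, so genotypes that
  would carry them are classified by the three-variant rule.
- Dosages are treated as unphased; the \*17-on-LOF-haplotype exclusion is
  a deterministic convention, not a phasing inference.
- The generator draws covariates independently, so it does not reproduce
  comorbidity correlation structure; the UM stratum is tiny at realistic
  cohort sizes and its estimated odds ratio is accordingly unstable (it is
  deliberately excluded from the recovered-effect checks).
- Wald intervals are reported even for sparse strata; the separation flag
  signals when they are unreliable, but no exact or penalized (Firth)
  inference is implemented.
- EHR linkage assumes the simplified coded-event schema described above;
  free-text prescriptions are matched by word prefix only.
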