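# Methods

## Deficit coding

A reference panel maps each of 22 routine blood variables to a normality
rule, sex-specific where clinical ranges differ (blood counts, red-cell
indices) and sex-free otherwise. Three rule shapes exist:

* **closed interval** `[lower, upper]` — a value is normal iff
  `lower <= v <= upper`. Endpoints are inclusive: a value exactly at a
  two-sided bound is *not* a deficit.
* **upper-only cut-off** `< x` — normal iff `v < x`, so a value exactly at
  the cut-off *is* a deficit (total cholesterol, triglycerides, LDL-C,
  direct bilirubin, ALT).
* **lower-only cut-off** `>= x` — normal iff `v >= x` (HDL-C), so the
  cut-off itself is normal.

The strictness of one-sided boundaries follows the printed inequality
direction of each rule and is configurable per entry. Units are metadata
only; no conversion is attempted, and reference-range estimation from data
is out of scope.

Two bundled panels differ in one cell: the default ships the published
female MCV lower bound of 32.6 fL verbatim; `panel_table3_mcv82` replaces
it with 82.6 fL, the clinically plausible value the 32.6 almost certainly
misprints. Nothing downstream depends on which panel is loaded; the
verbatim panel is the default so that published-table fidelity is the
baseline behaviour and the correction an explicit opt-in. Two other panel
entries are shipped as printed despite looking odd: neutrophils as a
percentage range (50–70%) and a direct-bilirubin cut-off of 3.4 µmol/L.

Missing labs code as missing; unknown lab keys are logged and ignored; a
subject without a decodable sex cannot be coded (sex-specific ranges would
be unresolvable) and raises a data error.

## The index

`FI = n_deficits / n_considered`, where the denominator counts the
non-missing panel variables for that subject. A score is **valid** only
when at least 70% of panel variables are non-missing — with fewer measured
items a 22-item index is dominated by noise — and the frail/non-frail
classification (cut-point 0.21, inclusive per the `>=` convention;
alternative cut-points 0.20–0.25 are accepted via configuration) is defined
only for valid scores. An all-missing vector yields an invalid result, not
a division by zero. The completeness rule is interpreted as a validity
condition on the subject, with the denominator remaining the number of
considered (non-missing) items; this keeps FI a ratio of reviewed deficits
and matches the construction lineage of laboratory frailty indices.

Cohort summaries (mean, SD, median, maximum, 99th percentile, frailty
prevalence) are computed over valid scores only. SD uses the n−1
denominator; percentiles use linear interpolation between order statistics
(the convention is oracle-tested, since none is fixed by the construction).

## Synthetic cohorts

The generator emulates the statistical structure of a community cohort of
736 subjects aged 90–108 (mean 93.6, SD 3.4, truncated normal), 67.5%
female, with FI mean 0.21, FI SD 0.10, ~50% frailty prevalence, 53.5%
4-year mortality and a frail-vs-non-frail hazard ratio of 1.32.

**Deficits** are exchangeable Beta-Bernoulli: subject i draws
`q_i ~ Beta(a, b)` with mean `p` and intraclass correlation `rho`
(`a + b = (1 - rho) / rho`), then each of the N panel variables is an
independent Bernoulli(q_i). The per-subject deficit fraction then has
variance `p(1-p)[1 + (N-1) rho] / N`, so `rho` is solved in closed form
from the target FI SD; the default `rho ≈ 0.0155` comes from
(p, SD, N) = (0.21, 0.10, 22). Exchangeability is a deliberate
simplification: no per-variable abnormality frequencies or inter-lab
correlations (e.g. haemoglobin–haematocrit coupling) are modelled, because
only the FI moments are calibration targets. Consequently the generator
reproduces the mean and SD of FI by construction but *not* data-dependent
order statistics (published median 0.23, maximum 0.55, 99th percentile
0.48) — a two-parameter calibration cannot pin those, and they are
documented as non-calibrated.

**Lab values** are realised from the deficit codes: a normal code draws
uniformly inside the subject's normal range; a deficit code draws outside
it with a bounded offset (25% of the interval width for two-sided ranges,
the side chosen at random; 50% of the cut-off value for one-sided rules),
floored at zero where the offset would cross it. Strict inequalities are
preserved at the draw level, and a recode-and-repair guard makes the
deficit → labs → deficit round trip exact for every seed. The values are
plausible in magnitude but make no claim of realistic marginal
distributions.

**Survival** is exponential within group under proportional hazards with
administrative censoring at 4 years — the simplest model that exactly
satisfies the proportional-hazards assumption the analysis fits. The
baseline (non-frail) rate λ solves

    (1 - prev) e^{-λt} + prev e^{-hr·λt} = 1 - target_mortality

by bracketed Brent root-finding (residual < 1e-10). `generate_cohort`
plugs in the *realised* frailty prevalence of the generated deficits
(≈ 0.49 under the defaults) rather than a nominal value, so simulated
mortality matches the 53.5% target by construction;
`calibrate_baseline_hazard` itself takes the prevalence as an argument.

**Covariates** (education in three levels, smoking, alcohol, exercise,
eight chronic-disease flags) default to the cohort-level prevalences of the
emulated study and are generated independently of frailty — the null
configuration, consistent with the near-identity of adjusted and unadjusted
hazard ratios it reports; optional per-covariate log-hazard effects support
adjusted-model testing. Missingness is completely at random, with a default
rate of 0: the emulated analysis sample was restricted to subjects with
complete blood panels, so complete labs are the faithful default, and tests
exercise nonzero rates explicitly.

All randomness derives from one integer seed through per-stage child
streams (demographics, deficits, labs, covariates, survival, missingness),
so cohorts are byte-identical across runs of the same seed.

## Survival analysis

Cox models are fitted by partial-likelihood maximisation (statsmodels
PHReg) with **Breslow ties by default** — matching the default of the SPSS
lineage of the emulated analysis — and Efron as an option. Hazard ratios
are exponentiated coefficients with 95% Wald intervals on the log scale; no
robust variance. The three adjusted models nest: model 1 adds age, sex and
education; model 2 adds smoking, alcohol and exercise; model 3 adds the
eight disease flags. Time origin is study baseline in years with
administrative censoring at 4.0; subjects lost to follow-up are excluded by
default (a censor-at-end policy flag exists in the reader contract).

The per-variable screen fits one univariate Cox model per panel deficit
code. Arms with fewer than `min_events_per_arm = 5` deaths are flagged
`unstable` rather than reported — rare deficits produce wild estimates
(compare a published screen row with HR 0.05, CI 0.01–4.52) — and constant
columns are `not_estimable`. Non-convergent fits (separation) are likewise
surfaced as unstable. In the orchestrated pipeline an adjusted model that
separates is reported "not estimable" instead of aborting the run;
constant covariates are dropped with a warning, while a constant exposure
is always an error.

Cumulative hazards use the Nelson–Aalen estimator (increment =
events / at-risk at each event time, from (0, 0)); it is implemented
directly — it is a five-line estimator — and cross-checked against
lifelines' unsmoothed estimator in the tests.

`recovery_experiment` is the validation harness: it repeats
generate → score → fit and reports the mean and SD of the estimates, the
bias of the log hazard ratio with its Monte-Carlo standard error, and
empirical 95% CI coverage.

## Comparison statistics

Pearson chi-square on 2×2 tables is **uncorrected by default**: the
uncorrected statistic reproduces published values recomputed from
reconstructed counts (22.6, 4.27), the Yates-corrected one does not;
correction is a flag. Proportion intervals default to the **Wilson score**
interval, which reproduces both printed prevalence bounds (46.9%, 54.1%)
where the Wald interval rounds the upper bound to 54.2%; both are
available. t-tests are pooled-variance by default (Welch optional) and are
computable from printed mean/SD/n summaries as well as raw data — the two
routes agree to floating point. Count reconstruction from printed
percentages rounds to the nearest integer and warns when a printed margin
is not matched. No multiple-testing correction is applied, matching
per-row testing at two-tailed 0.05.

Published t statistics for three comparisons (5.32, 2.23, 2.79) are not
recoverable from the printed rounded means/SDs (which give ≈ 5.08, 2.39,
2.71, presumably because the originals used unrounded data); the
recomputed values are what the tests assert.

## Problem sizes and tolerances

Monte-Carlo checks use 200 replicates of n = 736 for FI calibration and
hazard-ratio recovery (tolerance: three Monte-Carlo standard errors of the
replicate mean) and n = 50,000 for the mortality calibration check (three
binomial standard errors). Root-finding tolerances are 1e-14 absolute on
the bracketed hazard solve; the Cox grid-search oracle in the tests agrees
with the fitted coefficient to 1e-4. Empirical CI coverage over 200
replicates is accepted in [0.90, 0.99] (binomial noise around 0.95).

## Known limitations

* Exchangeable deficits ignore real inter-lab correlation structure and
  per-variable abnormality rates; passing calibration shows the FI moments
  and survival structure are right, not that individual lab marginals are.
* Exponential-within-group survival cannot probe proportional-hazards
  violations; diagnostics beyond a log–log plot helper are out of scope.
* No competing risks, time-varying covariates, unit harmonisation or assay
  QC; survival bias inherent to sampling nonagenarians is not modelled.
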