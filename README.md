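# filab

Laboratory-based frailty index (FI-LAB) scoring and mortality analysis for
very old cohorts.

## The problem

Frailty in older adults is commonly quantified by a **deficit-accumulation
frailty index**: the number of health deficits a person presents divided by
the number of deficits considered, a score between 0 and 1. Clinical frailty
instruments need time-consuming geriatric assessment; an attractive
alternative builds the index purely from **routine blood tests** — each lab
variable outside its clinical reference range counts as one deficit. For a
panel of N lab variables of which m are measured for a subject with d
abnormal results,

    FI-LAB = d / m,          valid only when m / N >= 0.70,

and a subject is classified **frail** when FI-LAB >= 0.21. The package
implements this construction for a 22-variable routine blood panel
(blood counts, liver and kidney chemistry, lipids, glucose), together with
the survival analysis that links frailty to 4-year mortality in a cohort of
community-dwelling nonagenarians and centenarians: Cox proportional-hazards
models (unadjusted and with three nested covariate sets), a per-variable
univariate hazard screen, Nelson–Aalen cumulative-hazard curves, and the
descriptive group comparisons (t-tests, Pearson chi-square, Wilson score
intervals for prevalences).

Because the source cohort is not publicly deposited, the package ships a
**calibrated synthetic-cohort generator**: exchangeable Beta-Bernoulli
deficits whose intraclass correlation is solved from

    Var(FI) = p (1 - p) [1 + (N - 1) rho] / N

to hit a target FI mean and SD (0.21 and 0.10 for N = 22 gives
rho ≈ 0.0155); lab values realised so that re-coding them reproduces the
deficits exactly; and exponential survival under proportional hazards whose
baseline rate is root-solved so overall 4-year mortality matches its target
(53.5%). Every downstream stage is therefore testable end to end from a
single seed.

## Worked example

```python
import pandas as pd
from filab import (SimulationConfig, generate_cohort, load_reference_panel,
                   code_cohort, score_cohort, summarise_fi,
                   fit_cox, ModelSpec, COVARIATE_SETS)

cohort = generate_cohort(SimulationConfig(seed=42))      # 736 subjects
panel = load_reference_panel()                           # 22-variable panel
scores = score_cohort(code_cohort(cohort, panel))
s = summarise_fi(scores)
print(f"n={s.n_valid}  FI mean={s.mean:.3f}  sd={s.sd:.3f}  "
      f"frail={100*s.prevalence_frail:.1f}%")

scored = pd.concat([cohort, scores], axis=1)
for name in COVARIATE_SETS:
    t = fit_cox(scored, ModelSpec("frail", name)).term("frail")
    print(f"{name:<11} HR {t['hr']:.2f}  "
          f"(95% CI {t['ci_lower']:.2f}-{t['ci_upper']:.2f})")
```

prints

```
n=736  FI mean=0.207  sd=0.099  frail=47.3%
unadjusted  HR 1.52  (95% CI 1.25-1.85)
model1      HR 1.52  (95% CI 1.25-1.86)
model2      HR 1.52  (95% CI 1.25-1.86)
model3      HR 1.53  (95% CI 1.25-1.87)
```

One seed is one cohort: the FI moments sit near their calibration targets
(0.21 / 0.10) and the single-cohort hazard-ratio estimate (here 1.52
against a true simulated value of 1.32) scatters with a Monte-Carlo
standard deviation of about 0.13 — averaging over replicates recovers the
truth (see below). The adjusted models barely move the estimate because
the covariates are generated independently of frailty. The same pipeline
runs from the shell:

```bash
filab simulate --n 736 --seed 42 --out cohort.csv
filab score cohort.csv --out scores.csv
filab analyze cohort.csv --out-dir run/    # models, tables, curves, manifest
filab report run/
```

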