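# iecvstage

Staging of myocardial fibrosis in aortic stenosis from cardiac-MRI T1
mapping, with the downstream survival analysis, exercised end-to-end on a
calibrated synthetic cohort.

In aortic stenosis (AS) the pressure-overloaded left ventricle hypertrophies
and progressively fibroses — first by diffuse expansion of the extracellular
matrix, ultimately by irreversible replacement scar.  Contrast-enhanced T1
mapping quantifies this process non-invasively.  This package is aimed at
imaging/biostatistics researchers who want a reproducible, tested
implementation of that staging analysis: the metric chain, the
control-anchored classification rule, and the person-years / Kaplan-Meier /
log-rank outcome statistics, together with a synthetic cohort generator so
the whole pipeline can be validated without patient data.

## The model

From six mid-cavity myocardial segments (native and 20-min post-contrast
T1), a blood-pool T1 pair and the hematocrit:

    ΔR1 = 1/T1_post − 1/T1_native
    λ   = ΔR1_myo / ΔR1_blood                    (partition coefficient)
    ECV = λ (1 − Hct)                            (extracellular volume fraction)
    iECV = ECV · (LV mass / 1.05 g·ml⁻¹) / BSA   (indexed extracellular volume, ml/m²)

BSA is Du Bois (`0.007184 · W^0.425 · H^0.725`).  Segments with mid-wall
late gadolinium enhancement (LGE) are analysed; segments with
infarct-pattern (subendocardial) LGE are excluded.

The upper limit of normal for iECV is anchored in healthy volunteers as
**mean + 2 SD** (≈ 22.5 ml/m² with control iECV 16.1 ± 3.2 ml/m²).
Patients are then staged hierarchically:

| stage | rule |
|---|---|
| excluded | infarct-pattern LGE (patient level) |
| unclassified | incomplete T1 mapping |
| replacement fibrosis | mid-wall LGE present (overrides iECV) |
| extracellular expansion | iECV ≥ threshold |
| normal myocardium | iECV < threshold |

Outcomes per stage: deaths, person-years, crude rates per 1,000
patient-years, Kaplan-Meier curves and a K-sample log-rank test (all
implemented from scratch; `lifelines`/`statsmodels` are used only as
cross-checks in the tests).  `iecvstage.stats` adds the surrounding
cohort statistics: descriptive group tables with normality-driven test
selection, iECV tertiles, Pearson/Spearman correlation, and logistic
(IRLS) / linear regression for adjusted associations such as the odds of
mid-wall fibrosis per ml/m² of iECV.

The synthetic generator inverts the observational design: a latent stage
is drawn first, then an internally consistent imaging panel (the metrics
chain recovers the generated ECV and iECV to machine precision), plus
exponential survival with per-stage hazards and uniform administrative
censoring.  Defaults are calibrated to the published two-arm study
summaries (37 controls vs 166 AS patients; stage hazards 8/36/71 deaths
per 1,000 patient-years).

## Worked example

```sh
iecvstage all --seed 42 --outdir runs/demo
```

writes `cohort.csv`, `metrics.csv`, `staged.csv`, `stage_outcomes.csv`,
`km_curves.csv`, `report.md` and a reproducibility `manifest.json`.
With the default configuration and seed 42 the report reads:

```
iECV threshold (control mean + 2 SD): 22.4 ml/m^2

stage        n   %
normal       68  51
expansion    31  23
replacement  35  26
Excluded: infarct-pattern LGE n=27, incomplete T1 mapping n=5

      stage  n  deaths  as_related_deaths  person_years  rate_per_1000py  as_rate_per_1000py
     normal 68       1                  0         186.1              5.4                 0.0
  expansion 31       1                  1          92.6             10.8                10.8
replacement 35       5                  4          88.8             56.3                45.0

All-cause log-rank: chi2=8.24, df=2, p=0.01621
AS-related log-rank: chi2=8.66, df=2, p=0.01315
```

Reading: the threshold derived from the 37 simulated controls
(22.4 ml/m²) splits the 134 classifiable patients into 51 % normal
myocardium, 23 % extracellular expansion and 26 % replacement fibrosis;
all-cause mortality climbs roughly tenfold from the normal to the
replacement stage, and the log-rank test rejects equal survival across
stages.  At n = 166 the death counts are small, so rates are noisy;
the calibration-scale runs below pin them down.

The same steps are available individually
(`iecvstage generate | metrics | stage | outcomes`) and as library calls
(`generate_cohort`, `compute_cohort_metrics`, `FibrosisStager().fit(...)`,
`stage_cohort`, `stage_outcomes`).

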