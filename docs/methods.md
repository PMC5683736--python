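# Methods

This note documents the models, conventions and design choices behind
`iecvstage`, in the spirit of the methods documentation of statistical
simulation packages: what is computed, under which assumptions, and what
passing tests do and do not establish.

## The metric chain

Per subject the inputs are ROI-level T1 values — six mid-cavity
myocardial segments (native / 20-min post-contrast), one blood-pool pair
— plus hematocrit, LV mass, height and weight.

- **Segment inclusion.** Segments carrying mid-wall LGE are analysed;
  segments with infarct-pattern (subendocardial) LGE are excluded.  A
  panel with zero usable segments yields a "metrics unavailable" state
  that staging maps to `unclassified` rather than an error.
- **Averaging.** Segment T1s are averaged arithmetically *before*
  conversion to R1 = 1/T1 (one ROI copied across maps), not averaged as
  per-segment λ values.  The alternative ordering differs only at
  second order in the segment spread; the choice is documented here and
  isolated in `compute_ecv_metrics`.
- **Partition coefficient and ECV.** λ = ΔR1_myo/ΔR1_blood and
  ECV = λ(1 − Hct): the standard contrast-equilibrium identities.
  These are the only formulations consistent with the jointly quoted
  group values (λ ≈ 0.45–0.47 with Hct ≈ 0.40 giving ECV ≈ 26–28 %).
  Non-positive blood ΔR1 (post ≥ native) is rejected as
  non-physiologic contrast kinetics.
- **Hematocrit** is a per-subject *input*; the package takes no position
  on same-day versus surrogate hematocrit.  The generator draws
  Hct ~ N(0.41, 0.03) truncated to [0.25, 0.55], a conventional adult
  range, because the emulated study reports no hematocrit summary.
- **Myocardial volume** is LV mass / 1.05 g·ml⁻¹ (standard CMR myocardial
  density).  The density is a configuration constant
  (`myocardial_density`), since mass-from-contours versus direct volume
  measurement cannot be distinguished from published summaries.
- **iECV** = ECV × myocardial volume / BSA (Du Bois).  Units ml/m².
  Reported at 1 decimal place, percentages as integers, with half-up
  rounding (clinical-table convention; `utils.round_half_up`).

## Staging rule

The iECV upper limit of normal is the control mean + 2 × sample SD
(n − 1 denominator — the conventional choice for reference ranges; the
denominator is not identifiable from the published 22.5 ml/m², which both
conventions reproduce at 1 d.p.).  Classification is hierarchical:
patient-level infarct-pattern LGE excludes a subject from staging even
when some segments remain usable (this is what makes the exclusion
arithmetic 166 − 22 − 5 = 139 work); incomplete T1 data is
`unclassified`; mid-wall LGE dominates the threshold rule; otherwise
iECV ≥ threshold is `expansion` (boundary value inclusive, per the
"≥ 22.5" rule) and below it `normal`.  There is no probabilistic or
ROC-optimised staging — the reference-range rule only.

`FibrosisStager` packages the rule as a scikit-learn estimator:
`fit(control_iecvs)` learns `threshold_`, `predict` maps
(iECV, LGE status) pairs to stages, and `fixed_threshold` bypasses
derivation for sensitivity analyses.

## Survival statistics

Person-years rates are crude: 1000 × deaths / Σ follow-up.  The
Kaplan-Meier estimator and the K-sample log-rank test are implemented
from first principles with the standard tie convention (deaths precede
censorings, i.e. subjects censored at t remain at risk for deaths at t).
The log-rank statistic is the quadratic form of observed − expected
event counts over the hypergeometric covariance, on K − 1 groups, with a
chi-square reference distribution for headline p-values; a permutation
null serves as the test-suite oracle (the chi-square p is asymptotic and
deviates from the exact permutation p by up to ~0.1 at n ≤ 10, which the
acceptance test allows for explicitly).  Cause-specific (AS-related)
analysis censors non-AS deaths; no competing-risks estimator and no Cox
model are provided, matching the unadjusted scope of the emulated
analysis (too few deaths for multivariable survival modelling).

## Cohort statistics

Shapiro-Wilk (α = 0.05, per group) routes each continuous variable to
mean ± SD with t-test/ANOVA or median (IQR) with
Mann-Whitney/Kruskal-Wallis; categoricals get chi-square.  Between-group
tests across the three iECV tertiles are plain K-group tests; no ordered
"trend" test is used because the emulated tables do not name one.
Tertile boundaries sit at the ⌈n/3⌉-th and ⌈2n/3⌉-th order statistics
with lower-boundary-inclusive tie assignment, so 161 distinct values
split 54/54/53 and heavy ties trigger a degeneracy warning instead of
silent rebalancing.  Logistic regression is Newton/IRLS with Wald CIs
and explicit divergence detection for separation; linear regression is
least squares with classical covariance.  Both are implemented in the
package (not wrapped) so that closed-form and grid-search oracles can
validate them; scipy supplies the classical univariate tests and
correlation p-values.

## The synthetic cohort generator

The generator defines the study conditions under which everything is
tested.  Structure, in generation order:

1. **Arms.** 37 controls and 166 AS patients by default.  AS severity is
   multinomial (34/45/87 mild/moderate/severe); mid-wall LGE prevalence
   rises with severity (2/34, 14/45, 28/87), reproducing the overall
   44/166 ≈ 27 % prevalence.  Exclusion overlays are drawn
   independently: incomplete T1 (5/166) and infarct-pattern LGE
   (22/166).  Non-LGE classifiable patients are `expansion` with
   probability 31/102, else `normal`.
2. **Latent-stage-first inversion.** The real study observes stages; the
   generator draws them first and then synthesises consistent data, so
   staging recovery is testable.  Per-stage iECV distributions are
   truncated normals — normal 18.3 ± 2.5 (truncated below 22.5 ml/m²),
   expansion 25.4 ± 3.1 (truncated above 22.5), replacement 30.4 ± 8.2 —
   so the latent stage is exactly recoverable by the 22.5 ml/m² rule
   (a 10⁻⁶ ml/m² guard band keeps floating-point noise off the
   boundary).  Truncation shifts realised means (≈ 18.0 / 26.4 / 30.5);
   the strict ordering across stages is preserved and asserted.
3. **Calibration identity.** The two-arm means (16.1 vs 23.6 ml/m²) and
   the per-stage means cannot both be hit by the classifiable mixture
   alone (it averages ≈ 23.2).  The infarct-excluded subgroup therefore
   carries its own iECV distribution, mean parameter 25.8 (truncated
   mean ≈ 26.0), chosen in closed form so the AS-arm marginal mean is
   23.600 — physiologically sensible (prior infarction with remodelling
   sits between expansion and replacement) and fixed once, analytically.
4. **Consistent panels.** ECV fraction is drawn per stage
   (≈ 26.5 / 26.3 / 26.9 / 29.1 % for control/normal/expansion/
   replacement); LV mass index is *derived* as iECV·ρ/ECV rather than
   drawn, which keeps ECV physiologic by construction and lands the
   emergent LVMi means (≈ 64/75/103/109 g/m²) on the published
   62/73/96/107 pattern without separate tuning.  Segmental T1s are
   back-solved from λ with zero-sum noise over usable segments, so the
   metrics chain recovers the generated ECV and iECV to machine
   precision (the round trip is asserted at 10⁻⁹).
5. **Survival.** Event times are exponential with stage hazards
   0.008/0.036/0.071 per person-year (the published 8/36/71 per 1,000
   patient-years); controls use 0.005.  Administrative censoring is
   uniform on 1.3–4.5 years (mean 2.9, SD ≈ 0.9, emulating the reported
   2.9 ± 0.8-year follow-up).  Crude deaths/person-years is exactly
   unbiased for an exponential hazard under independent censoring, which
   is what the simulation-recovery check exploits.  AS-related death
   flags are Bernoulli per stage (0 / 1.0 / 0.75), reproducing the
   0 / 36 / 52 cause-specific rate pattern.
6. **Biopsy subset.** 11 stageable AS patients are sampled;
   histology %fibrosis = −10.3 + 1.0 × iECV + N(0, 4.0), truncated to
   [0, 100].  The slope/intercept are the least-squares line through the
   published per-stage histology means (≈ 8.9/12.4/22.4 %); the noise SD
   of 4.0 sets the population correlation to ≈ 0.87 given the AS-arm
   iECV spread (σ ≈ 7.1): ρ = σx/√(σx² + 4²) ≈ 0.87.  Tests check the
   n = 11 sampling distribution of r is centred in this regime, not any
   single r value.
7. **Seeding.** One integer seed drives a single `numpy` PCG64 stream in
   a fixed draw order; identical (config, seed) gives byte-identical
   CSVs.  The biopsy sampler derives a sub-seed so biopsy replication
   does not perturb the cohort stream.

### What the generator does not emulate

Truncated-Gaussian marginals are conventions — the emulated study
publishes only means/SDs/medians, so higher moments, within-subject
correlations beyond those built in (iECV–LVMi–ECV consistency, stage
links), measurement error in T1, multi-site batch effects, informative
censoring and competing risks are all absent.  Passing tests therefore
demonstrate the *analysis code* is correct under the declared data model,
not that the clinical findings would replicate on real patients.

## Problem sizes and tolerances

Law-of-large-numbers checks use 5,000 subjects per arm (arm means within
3 SE of targets) and 5,000 per stage for hazard recovery (rates within 3
Poisson SEs of 8/36/71; the three-group log-rank rejects far below
10⁻³).  The permutation oracle uses 10⁵ label permutations on fixtures
of n ≤ 10.  Numerical conventions: IRLS converges at step-norm 10⁻¹⁰
with divergence declared when |η| exceeds 40; the log-rank covariance is
inverted by pseudo-inverse to tolerate degenerate groups; exact-identity
assertions (iECV chain, round trips) use 10⁻⁹ relative tolerance;
boundary classification is exact (≥ threshold is expansion).
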