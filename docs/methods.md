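# Methods

## The scaling problem

Peak oxygen uptake (VO₂peak) is conventionally indexed to total body
mass (ml·kg⁻¹·min⁻¹). Total mass includes fat and other tissue that
consumes little oxygen at peak exercise, so mass-indexing systematically
understates cardiorespiratory fitness in women, older adults and people
with obesity. `ebmscale` implements an alternative scaling metric,
**exercise body mass (EBM)**, an allometric combination of mass, height,
sex and age intended to track metabolically active tissue:

```
EBM = Mass(kg)^0.63 · Height(m)^0.53 · 1.16^[male] · exp(−0.39 · fAge²),
fAge = Age/100
```

together with an HRR-aware treadmill **workload** (WL) estimate in METs,

```
WL = 2 + Sp(mph) · (1.06 + 5.22 · fGr) + 0.019 · HRR(bpm)
```

and the generalized prediction

```
VO₂peak (ml·min⁻¹) = 11 · EBM · WL
```

where 11 ml·min⁻¹ per EBM unit is the oxygen cost of one MET. The
constant is derived, not free: for a reference man of height 1.75 m, BMI
25 (76.6 kg) and age 20, one MET costs 3.5 · 76.6 ml·min⁻¹; dividing by
his EBM (≈ 23.64) gives 11.34, rounded to 11
(`recompute_met_constant`). The intercept of 2 METs (rather than the 1
MET resting term of the classic speed/grade formula) reflects the poor
economy of slow locomotion; consequently the HRR-aware WL exceeds the
comparator at the low end, and the comparator regresses on it with a
through-origin slope below 1.

All coefficients live in one frozen `ScalingConstants` dataclass and can
be overridden per call or from a flat YAML/JSON file for refit
experiments; the defaults are the published values.

## Synthetic cohorts

No public registry provides per-subject treadmill speed, grade, HRR and
measured VO₂peak, so the package ships a first-class simulator
(`simulate.py`). A cohort is drawn from sex-stratified truncated normal
distributions whose means/SDs are the published summary statistics of a
large US CPX registry (healthy stratum: age 44 ± 13 y truncated to
18–79, height 1.78 ± 0.07 / 1.65 ± 0.06 m, BMI 26 ± 4 truncated to
18.5–40 with mass = BMI·height², speed 5.4 ± 1.6 / 4.0 ± 1.1 mph, grade
0.11 ± 0.05 / 0.12 ± 0.04, HRR 112 ± 17 / 103 ± 20 bpm, RER 1.17 ± 0.10
truncated at 0.9, 57% men, n = 5,618; CVD/HF presets use the CVD
stratum). VO₂peak is generated from the model itself:

```
VO₂peak = s · 11 · EBM · WL · exp(ε),   ε ~ N(0, σ²)
```

with σ = 0.17 by default — chosen so the log-linear derivation model's
R² on default synthetic data lands near 0.82, the neighbourhood of the
registry value — and s ≤ 1 a slope factor for heart-failure cohorts
(default preset 0.9, matching the ~10% HF underperformance per unit
workload that remains after HRR adjustment).

Joint structure: only marginal moments are published, so covariate
dependence is a modelling choice. Speed, HRR and peak HR get a mild
linear age decline (−0.04 mph/y, −0.8 bpm/y, −0.7 bpm/y) with the
residual SD shrunk to preserve the marginal SD; sex differences enter
through the sex-specific means. Sampling is inverse-CDF on the truncated
range, so output is byte-identical under (spec, seed). Resting HR is
reconstructed as hr_peak − HRR (floored at 30 bpm, with hr_peak shifted
to preserve the HRR identity exactly).

The DXA cohort (ages 20–50, BMI 25–40, n = 466) generates lean body
mass as LBM = (1.61·EBM)^(1/0.9) · exp(η), η ~ N(0, 0.05²), so the
through-origin relation LBM^0.9 = 1.61 · EBM is recoverable by
construction (observed r ≈ 0.97) and LBM < total mass always.

What the simulator does *not* emulate: race/ethnicity structure,
protocol/ramp selection and handrail effects, athlete or sarcopenia
body-composition extremes, and any real covariance between
anthropometrics and test variables beyond the age links above. Passing
recovery and calibration tests therefore demonstrates internal
correctness of the estimators under the stated generative model, not
registry-level validity.

## Derivation procedures

`fit_ebm_model` regresses ln VO₂peak on ln mass, ln height, a male
indicator, fAge, fAge², fAge³ and exercise covariates, then removes the
single worst p > 0.05 term per iteration (ties broken by larger p, then
term name — fully deterministic). The retained ln-mass, ln-height, male
and fAge² coefficients are exponentiated into the multiplicative form;
retained fAge/fAge³ terms are reported but not folded into the canonical
expression. A pooled-vs-full-sex-interaction nested F-test p-value is
reported. Weights are uniform by default with an optional weight vector.

Exercise covariates enter in one of two modes:

- `"raw"` (default): speed, grade and HRR enter linearly on the log
  scale — the published procedure. Since ln WL is not linear in these
  variables this model is deliberately approximate; on synthetic data it
  still recovers the body-size exponents without material bias.
- `"log_workload"`: ln WL enters as one regressor. Under the simulator
  this model is exactly identified, so it is the mode used for
  parameter-recovery validation (with σ = 0, coefficients are recovered
  to ≤ 1e−8).

The three fAge terms are heavily collinear over ages 18–79; with noisy
data backward elimination may keep a different member of the age family
than fAge² while the body-size terms remain stable. This is expected and
reported rather than hidden.

`fit_workload_equation` regresses VO₂peak/(11·EBM) on speed, speed·grade
and HRR with intercept. `fit_additive_approximation` fits the per-sex
linear plane EBM ≈ b₀ + b₁·mass + b₂·height + b₃·age and flags validity
at R² ≥ 0.99 (observed ≈ 0.999 on default cohorts; maximum pointwise
deviation from the allometric form ≈ 8% over the realistic cohort
distribution, with >10% possible at implausible corner combinations of
heavy+short+old).

### Pre-registered recovery tolerances

Tolerances for noisy-recovery tests were fixed from a 200-replicate
pilot (n = 5,618, σ = 0.17, replicate seeds 10000–10199) as
|Monte-Carlo bias| + 4·SD, before the acceptance tests were written:

| parameter | truth | pilot bias | pilot SD | tolerance |
|---|---|---|---|---|
| mass exponent | 0.63 | +0.001 | 0.015 | 0.06 |
| height exponent | 0.53 | −0.003 | 0.066 | 0.27 |
| male factor | 1.16 | +0.000 | 0.008 | 0.035 |
| WL intercept | 2.0 | +0.024 | 0.175 | 0.75 |
| WL speed | 1.06 | +0.015 | 0.025 | 0.12 |
| WL speed·grade | 5.22 | +0.069 | 0.159 | 0.75 |
| WL HRR | 0.019 | +0.0004 | 0.0016 | 0.007 |

The height-exponent and WL-intercept spreads are dominated by structural
collinearity (ln mass = ln BMI + 2·ln height; speed with speed·grade),
not estimator defects; the pilot shows no systematic bias. The small
positive WL biases (~e^{σ²/2} − 1 ≈ 1.5%) come from regressing the
mean of WL·exp(ε) rather than its median; they are well inside the
bands.

## Evaluation framework

**Size independence** (`size_independence`): within each sex × WL bin
(men <7, 7–7.9, …, ≥15 METs; women <6, …, ≥12; EBM-based WL defines the
bins, configurable), the Pearson correlation between VO₂peak/scaler and
the scaler, with the exact two-sided t-transform p at n−2 df and a
display significance threshold of p < 0.01 (no further multiplicity
correction). Bins with n < 3 or zero variance report r as NaN with a
warning. On default synthetic data mass-indexing is negatively
correlated in essentially every bin while EBM-indexing shows no
significant bin — the qualitative pattern that motivates the metric.

**Calibration** (`calibration_slopes`): per sex × age band (<40, 40–60,
>60) × BMI band (<25, 25–30, >30), the through-origin slope Σxy/Σx² of
measured on predicted VO₂peak, with SE and t-based CI; the mean of
per-subject ratios is reported alongside because "mean slope" is
ambiguous — the regression slope is the headline. Cells aggregate
unweighted; the overall slope and Pearson r are computed on the full
cohort. Under the generator with σ = 0 every slope is exactly 1; with
multiplicative noise slopes sit near E[e^ε] ≈ 1.015.

**Contrasts** (`subgroup_contrasts`): relative mean ratios (%) and
Cohen's D (pooled SD) of MET-standardised indexed VO₂peak (constants
3.5 for mass, 11 for EBM) for men vs women at BMI < 25, BMI < 25 vs
> 30, and age < 40 vs > 60. On default synthetic data the sex gap's |D|
shrinks from ≈ 1.0 (mass standard) to ≈ 0.7 (EBM standard) because the
EBM standard retains only the genuine workload difference.

**HF slopes** (`hf_slope_analysis`): calibration reports for a healthy
and an HF cohort plus their overall-slope ratio and a direction flag.

**Workload comparison** (`compare_workload_formulas`): through-origin
slope of the comparator WL on the HRR-aware WL (≈ 0.90 on default
synthetic data, inside the 0.8–1.0 band around the registry's 0.88) and
a per-decile difference profile confirming the HRR-aware formula is
higher at low workloads.

## Numerical choices and degenerate inputs

- EBM is evaluated in log space; log-space and direct-power evaluation
  agree to ≤ 1e−12 relative error (tested).
- Truncated-normal draws use `scipy.stats.truncnorm.ppf` on uniform
  variates (inverse CDF), never rejection, for seed-stable output size.
- Zero-variance guards use a relative 1e−12 threshold so exactly
  proportional constructions report undefined correlation rather than a
  numerically meaningless one.
- Perfect fits (σ = 0) produce degenerate p-values; elimination treats
  NaN p as 0 (keep), so exact identification is unaffected.
- Heights > 3 m and fractional grades > 1 are rejected with unit hints
  (centimetres / percent); sex must be a literal string.
- Cohen's D with zero pooled variance is NaN; through-origin slope with
  Σx² = 0 raises.

## Problem sizes

Default analyses run at the design size n = 5,618 (healthy) and
n = 1,007 (HF), which complete in seconds; unit tests use n = 150–2,000
cohorts, and replicate studies use 50–200 seeded repetitions.

## Known limitations

- The additive EBM coefficients are reproduced as printed; the original
  fitting weights are unpublished, so re-derivation from a cohort gives
  slightly different (equally valid) planes.
- Raw-mode derivation is structurally misspecified for the workload part
  of the model (see above); its age-term estimates in particular should
  not be over-interpreted.
- Registry-level quantities (R², r, per-bin correlation values) are not
  reproducible from synthetic data and are treated only as qualitative
  direction checks.
- Percent-predicted VO₂, VE/VCO₂ slope and cycle-ergometer equations are
  out of scope; a "%predicted HR" column, if present, passes through I/O
  untouched.
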