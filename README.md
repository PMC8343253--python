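# growthkit

Pediatric growth analytics for cohort studies of obesity and linear growth:
LMS-based z-score referencing, construction of weight-group-specific height
centiles, growth-velocity analysis with registry-style plausibility filters,
stratified weight-group contrasts, cross-lagged BMI–height effect
estimation, and piecewise random-intercept trend models — together with a
synthetic cohort generator that plants a known obesity effect profile so
every stage of the pipeline can be validated end to end without access to
individual-level clinical data.

## Who this is for

Biostatisticians and auxologists analysing mixed cross-sectional/
longitudinal pediatric cohorts (ages 0–18) who need to (a) reference
anthropometry against LMS tables, (b) compare normal-weight and obese
strata across age groups with familywise error control, (c) quantify
growth-velocity dynamics (accelerated prepubertal growth, blunted pubertal
spurt), and (d) build obesity-specific height reference curves.

## The models

**LMS referencing.** A reference distribution is summarised by three
age- and sex-specific curves — Box-Cox power *L(t)*, median *M(t)*,
coefficient of variation *S(t)*. A measurement *x* at age *t* maps to a
standard deviation score

```
z = ((x/M)^L − 1) / (L·S)    (L ≠ 0),        z = ln(x/M)/S    (L = 0)
```

with exact inverse `x = M(1 + L·S·z)^{1/L}` and centile `Φ(z)·100`.
Weight categories follow the BMI-SDS cutoffs −1.28 / 1.28 / 1.88
(underweight / normal / overweight / obese).

**Centile estimation.** `fit_lms` estimates smooth L, M, S curves from
cross-sectional (age, value) data by penalized maximum likelihood of the
Box-Cox normal model, `ℓ = L·ln(x/M) − ln S − z²/2`, with cubic-B-spline
curves, second-derivative smoothness penalties expressed as target
effective degrees of freedom, and alternating penalized-Newton updates
whose step-halving guarantees monotone ascent.

**Velocity analytics.** Growth velocity is the height change between
consecutive visits divided by the elapsed time (interval 3 months–2 years,
mean age ≥ 1.5 y), with plausibility exclusions (negative velocity;
< 1 cm/y under age 14; velocity SDS > 10). Per-age-group contrasts use
Welch t-tests with step-down Holm–Šídák correction
(`adj_(i) = 1 − (1 − p_(i))^(m−i+1)` with running maximum) and suppression
of strata with N < 6.

**Cross-lagged effects.** Per one-year age group, OLS of height SDS at
*t* + 1 on BMI SDS at *t*, adjusted for height SDS at *t*; the coefficient
β₁ is the cross-lagged effect in SDS per BMI SDS.

**Piecewise trends.** Within piecewise age intervals (boys
2.0–4.99/5.0–10.99/11.0–17.0, girls 2.0–8.249/8.25–10.99/11.0–17.0 y),
height SDS ~ age × weight group (optionally + mid-parental height SDS and
birth length SDS) with a subject-level random intercept, fitted by REML
with a 1-D profile over σ²_b/σ²_e.

## Worked example

```python
import growthkit as gk

refs = gk.default_reference()
cohort = gk.generate_cohort(
    gk.GeneratorConfig(n_normal=2000, n_obese=2000, seed=1,
                       include_analytes=False),
    gk.EffectProfile(), refs)
annotated = gk.annotate_observations(cohort.children, cohort.observations, refs)
filtered, log = gk.apply_inclusion_filters(cohort.children, annotated)
print(f"observations kept: {log['observations_out']} of {log['observations_in']}")

first = gk.dedup_first_per_group(filtered)
girls = first[first.sex == "female"]
height = gk.compare_groups(girls, "height_sds", "obese", "normal")
group, diff = gk.max_group_difference(height, metric="sds", window=(2, 10))
print(f"girls: largest height-SDS gap {diff:.2f} SDS at age group {group}")

velocities, _ = gk.compute_velocities(filtered, refs[gk.VELOCITY])
velocities = gk.dedup_first_velocity_per_group(velocities)
boys_v = gk.compare_groups(velocities[velocities.sex == "male"],
                           "gv", "obese", "normal")
print(f"boys: pubertal velocity reduction "
      f"{gk.window_mean_reduction(boys_v, (13, 14)):.1f}% (ages 13-14)")

normal_ids = cohort.children.loc[cohort.children.stratum == "normal", "child_id"]
pairs = gk.build_cross_lag_pairs(filtered[filtered.child_id.isin(normal_ids)])
effect = gk.cross_lag_effect(pairs).table.set_index("age")
print(f"BMI SDS -> next-year height SDS at age 1: "
      f"beta = {effect.loc[1, 'beta']:.3f} (SE {effect.loc[1, 'se']:.3f})")
```

prints

```
observations kept: 52364 of 52912
girls: largest height-SDS gap 1.43 SDS at age group 7
boys: pubertal velocity reduction 24.3% (ages 13-14)
BMI SDS -> next-year height SDS at age 1: beta = 0.175 (SE 0.019)
```

The generator plants a girls' height offset peaking at 7.6 cm (≈1.4 SDS),
a 25% pubertal velocity reduction for boys, and a cross-lag coefficient of
+0.18 at age 1; the pipeline recovers each within sampling error. A small
fraction of observations is removed by the inclusion rules (height SDS
outside [−2.5, 4.0], BMI SDS < −3.5, prematurity before age 2).

A command-line interface mirrors the library:

```bash
growthkit simulate --n-normal 2000 --n-obese 2000 --seed 1 --out run/cohort
growthkit reference-sds --cohort run/cohort --out run/annotated
growthkit analyze --cohort run/annotated --out run/analysis
growthkit fit-reference --input run/cohort/observations.csv --seed 1 --out run/ref
growthkit report --run run/analysis --out run/summary.json
```

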