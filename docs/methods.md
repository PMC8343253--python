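# Methods

This note documents the statistical models implemented in growthkit, the
design of the synthetic cohort generator used to validate them, and the
numerical and design choices that were genuinely open.

## LMS referencing

Measurements are referenced by Cole's LMS method: the reference
distribution of a measure at age *t* (sex-specific) is Box-Cox normal with
power L(t), median M(t) and coefficient of variation S(t), and

    z = ((x/M)^L − 1)/(L·S)   for L ≠ 0,      z = ln(x/M)/S   for L = 0.

Tables are supplied as CSV (`measure,sex,age,L,M,S`) and interpolated
**linearly in age per component**. Linear interpolation was chosen over
cubic because it reproduces published-table conventions bit-exactly and
keeps exported centile tables reproducible from the table alone; the
synthetic default reference is tabulated every 0.1 y, so the difference
from smooth interpolation is below 0.01 cm. Lookups outside a table's age
range raise; the pipeline clips lookup ages to the table range only for
the open-ended 18+ age group.

BMI is computed as weight[kg]/height[m]² before referencing. Weight
categories use BMI-SDS cutoffs −1.28 / 1.28 / 1.88 with the boundary
conventions: −1.28 and 1.28 are normal-weight, 1.88 is overweight.
SGA/AGA/LGA classification of birth size uses ±1.28 SDS by default
(≈10th/90th centile); the cutoffs are configurable because conventions
differ between registries (±1.28 and ±2 SDS are both in use), and a
missing gestational age yields `unclassified` rather than an error.

## Centile curve estimation

`fit_lms` maximizes the penalized Box-Cox log-likelihood

    Σᵢ [ L(tᵢ)·ln(xᵢ/M(tᵢ)) − ln S(tᵢ) − zᵢ²/2 ]  −  ½ Σ_c α_c ∫ c″(t)² dt

over cubic-B-spline coefficient vectors of the three curves. L and M are
linear in the basis; **S is parameterized on the log scale** (the penalty
applies to (ln S)″) so positivity is structural. Optimization alternates
one penalized Newton (scoring) step per curve (order M, S, L) with
per-observation analytic gradients, finite-difference curvatures clipped
to be positive, and step-halving against the penalized likelihood — which
makes the criterion non-decreasing across sweeps by construction.
Initialization is fixed (L ≡ 1, M from binned running medians, S from
binned running CVs), so fits are deterministic given data and
configuration. Non-convergence within `max_iter` is reported via
`converged=False`, not raised.

Smoothness is specified as target effective degrees of freedom (EDF) per
curve and converted to penalty weights by solving
trace((BᵀWB + αP)⁻¹BᵀWB) = EDF once at initialization. Defaults are
EDF (L, M, S) = (4, 14, 4) with 15 interior knots placed at quantiles of
√age. The large M budget and the √age knot placement are deliberate: no
age-power transformation of the time axis is applied, so the steep infancy
segment of a 0–18-y height median (≈25 cm in the first year) must be
carried by the spline itself; with uniform-quantile knots and EDF ≤ 12 the
fitted median was still ~1 cm off at age 1 in recovery checks, while
(4, 14, 4) with √age knots recovers the generating median to well under
1 cm everywhere on ages 1–17 and holds the nominal 3% tail coverage.
For reference construction from longitudinal data, one randomly selected
observation per child is used (seeded, logged).

Not implemented (out of scope): worm-plot/Q-statistic diagnostics,
age-power transformation, bootstrap confidence bands, and
skewness-kurtosis (BCPE/GAMLSS) extensions beyond the Box-Cox normal.

## Cohort pipeline

**Inclusion rules** (each an independent row predicate, so filter
composition is order-free): height SDS within [−2.5, 4.0]; BMI SDS
≥ −3.5; children born before gestational week 38 contribute observations
only from age 2.0 onward; children flagged with growth-affecting disease
or medication are excluded entirely. Metformin and thyroxin flags are
analyte-specific: they remove only insulin/glucose/HOMA-IR and TSH/FT4
rows respectively. The exclusion log counts each rule separately.

**Age groups** by rounded age: group g covers [g−0.5, g+0.5) for
g = 1…17; ages ≥ 17.5 form the open-ended group 18+. Ages in [0, 0.5)
form group 0 — the interval convention extrapolated downward, since the
enumeration otherwise starts at group 1 while age-0 data exist. One
observation per child per age group (the youngest; ties by input order)
enters cross-sectional displays and tests; the operation is stable and
idempotent.

**Velocities** come from consecutive visit pairs (no skipping over an
intermediate visit; overlapping chains allowed): gv = Δheight/Δt with
interval in [0.25, 2] years, assigned to the mean age (mean age ≥ 1.5 y).
Plausibility filters: gv < 0 always; gv < 1 cm/y under mean age 14;
velocity SDS > 10. If no velocity reference is supplied, the SDS filter is
skipped with a warning and logged. The weight category of a velocity
record is taken from the earlier observation of the pair by default; the
alternative (child's first-ever visit) is available via
`VelocityConfig(weight_rule="child-first")` because the source convention
is ambiguous.

**Contrasts.** Per age group, two-sample t-tests — Welch by default
(pooled variance via `equal_var=True`) since the unpaired t-test variant
is otherwise unspecified — with step-down Holm–Šídák correction across
the non-suppressed age groups of one outcome × sex panel (matching
per-panel significance marking; cross-outcome correction was rejected).
Strata with N < 6 in either group are suppressed and excluded from the
correction family. Zero variance in both groups flags the stratum as
degenerate with an undefined p.

`window_mean_reduction` reports the percent reduction averaged over a
window's age groups. When an effect is constant across a window, this
estimates the window's maximum reduction without the upward bias that the
extremum of noisy per-group cells carries (the max of k unbiased cells
overshoots by roughly E[max of k noise terms]); the per-age extremum
remains available via `max_percent_reduction`.

## Growth models

**Mid-parental height** is the mean of the parents' adult height SDS,
each referenced against the adult end of the sex-specific height table.
Averaging in SDS space already sex-normalizes, so no ±6.5 cm child-sex
correction is applied (the cm-space convention would reintroduce the
child's sex into a quantity that is about the parents). One missing
parent falls back to the other's SDS; both missing withholds adjustment.
Adjusted height is child SDS − mid-parental SDS (linear, invertible).

**Cross-lagged effect.** Pairs are built from the first observation per
child in consecutive age groups (g, g+1); children lacking g+1 contribute
nothing, and the 18+ group is never a starting point. Per age group, OLS
of height SDS at t+1 on {1, BMI SDS at t, height SDS at t}; β₁ is
reported with its SE and two-sided p. Significance is judged uncorrected
per age (the convention for per-age significance marking); Holm–Šídák
across ages is available via `adjusted=True`. The reversed direction
(height → next-year BMI) runs through the same operation with roles
swapped. Note that with strata of very different BMI means, the pooled β₁
mixes within- and between-stratum variation; planted-coefficient recovery
is therefore checked within the normal-weight stratum, where BMI deviations
are mean-centered (see the generator section).

**Random-intercept model.** y = Xβ + b_subject + e with b ~ N(0, σ²_b),
fitted by REML. The variance ratio θ = σ²_b/σ²_e is profiled: given θ,
V_i⁻¹ = I − (θ/(1+θn_i))J per subject gives closed-form GLS for β and
σ̂²_e, and the REML criterion is maximized over log θ by a deterministic
coarse grid plus bounded scalar refinement. θ̂ = 0 at the boundary reduces
exactly to OLS. Rank-deficient designs raise with the aliased column
names. The fit matches brute-force GLS on balanced designs to 1e-6 and
statsmodels MixedLM (REML) to numerical precision in tests.

**Piecewise trends.** Within fixed age intervals (boys 2.0–4.99 /
5.0–10.99 / 11.0–17.0; girls 2.0–8.249 / 8.25–10.99 / 11.0–17.0; the last
interval closes at 17.0, interior boundaries are half-open so 4.99 and
5.0 fall in different intervals), height SDS ~ age × group (+ optional
child-level covariates) with a random intercept per child, on the
multiple-observations data set. The covariate model is a **fixed reduced
model** (mid-parental height SDS + birth length SDS, no birth weight, no
covariate interactions) rather than automated stepwise deletion, keeping
the fit deterministic and matching the reduced specification. Wald tests
on the interaction are used; likelihood-ratio testing was the rejected
alternative (Wald is standard for single coefficients and avoids refits).
Intervals with fewer than two subjects in either group are skipped with a
warning.

## Endocrine module

HOMA-IR = insulin[mU/l] × glucose[mmol/l] / 22.5. Insulin is stored
canonically in pmol/L (as plotted); the conversion 1 mU/l = 6.945 pmol/L
is applied explicitly at the HOMA-IR boundary and logged — the conversion
factor itself is a convention the package fixes since assay documentation
varies between 6.0 and 7.175. Analyte contrasts reuse the comparison
machinery (family = analyte × sex), on raw concentrations by default (the
convention for displayed means); a log-scale option exists for skewed
analytes such as leptin and is off by default. Pubertal windows are
configuration (defaults: velocity windows boys 13–14 / girls 12–13;
late-pubertal estradiol 15–16), not hard-coded claims.

## Synthetic cohort generator

The generator exists so that every pipeline stage is testable without
access to clinical registries. It emulates a mixed cross-sectional/
longitudinal registry: first visit at age ~U(0.5, 4) (configurable), then
annual visits jittered ±0.15 y with per-visit retention 0.8 until age 18;
8% of children are premature (GA ~U(32, 37)), the rest term (U(38, 42)).

**Reference set.** Height-for-age with L ≡ 1, S ≡ 0.042 and a monotone
cubic (PCHIP) median through sex-specific knots (boys 50 cm at birth to
177 cm at 18; girls 49.5 to 164); the velocity reference is the exact
derivative of the height median with SD 1 cm/y; the BMI reference
(L = 1, S = 0.11) makes the generator's latent BMI SDS round-trip exactly
through the pipeline's referencing; birth-size references are linear in
gestational age (SD 2 cm / 450 g). The calibration M·S ≈ 4.87 cm at
(boys, 6 y) and ≈ 5.38 cm at (girls, 8 y) ties the planted cm offsets to
their SDS counterparts (6.8/4.87 ≈ 7.6/5.38 ≈ 1.4 SDS).

**Latent height dynamics.** Each child has an intercept u ~ N(0, 0.95²)
SDS plus an Ornstein-Uhlenbeck wiggle around u (reversion 0.92/y,
innovation SD 0.15/√y, stationary SD ≈ 0.38), giving total height-SDS SD
≈ 1.02 and annual velocity noise ≈ 1 cm/y — consistent with the velocity
reference's SD. A pure random-walk update was rejected because its
variance grows without bound, contradicting the ~N(0, 1) height-SDS
distribution the referencing assumes at every age. The cross-lag kick
γ(t)·(BMI SDS − stratum mean)·Δt enters the persistent component, so the
planted γ(t) is exactly the conditional-mean coefficient that the
cross-lag regression estimates. γ operates on within-stratum deviations so
the stratum-level offset D(t) and the individual-level coefficient stay
separately identifiable; consequently planted-γ recovery is a
within-stratum property, and the recovery analysis simulates the
normal-weight stratum (in a pooled two-strata cohort the OLS coefficient
is attenuated by between-stratum BMI variance and confounded by the D(t)
drift — by design, not by accident).

**BMI paths** are stationary AR(1) (persistence 0.9/y) mapped through
per-stratum truncated normal marginals (normal: N(0, 0.65) on
[−1.28, 1.28]; obese: N(2.4, 0.35) above 1.88), so stratum labels agree
with recomputed BMI-SDS categories and persistence survives the
truncation.

**The planted offset D(t)** (obese minus normal mean height, in cm)
starts at the birth-length offset (0.5 cm — "slightly larger at birth"),
ramps its derivative from 0 at age 0.5 to the 1.2 cm/y plateau, and ramps
down so D(A_max) = D_max exactly (boys 6.8 cm at 6 y; girls 7.6 cm at
8 y). Ramp lengths are solved, not fixed: the boys' default is
infeasible with a 1-y ramp (maximum attainable 6.2 cm), so the up-ramp
shortens as needed; profiles whose D_max exceeds the d→0 attainable bound
raise with that bound. D is flat to age 11, then declines via a smooth
bump per pubertal-window age group plus a wide parabola, with
coefficients solved linearly so that (a) the obese stratum's
interval-averaged mean velocity over each window group equals the planted
ratio (0.75 boys, 0.78 girls) times the normal stratum's and (b)
D(17) equals the 0.3 cm convergence residual. The constraints are imposed
on 1-year interval averages because that is what a velocity record
measures. Planting in cm (not SDS) keeps the cm and SDS readouts jointly
coherent through the calibrated reference.

One known attenuation: the gv < 1 cm/y under-14 plausibility filter
truncates the obese stratum's lower velocity tail inside the girls'
window, raising its post-filter mean slightly; the recovered girls'
reduction therefore sits ~1 pp below the planted 22%. This is a faithful
consequence of running the exclusion rules on a blunted stratum, not a
generator defect.

**Analytes** use plausible textbook age profiles (IGF-1 rising to a
pubertal peak of 380 ng/mL in boys at 13.5 y / 420 in girls at 12.5 y;
testosterone logistic 0.5→18 nmol/L, midpoint 13.5 y; estradiol logistic
20→350 pmol/L, midpoint 12.5 y; age-increasing insulin and leptin
medians) with mean-preserving log-normal noise (CV 0.35) and obese-stratum
multipliers (IGF-1 ×1.10 at ages 6–9 and ×0.83 in the pubertal window;
testosterone ×0.38 in the boys' window recovering to ×0.9 by 17;
estradiol ×0.63 at girls 15–16; insulin ×2.5; leptin ×4). The curves are
deliberately not fitted to any published figure; only the planted
multipliers carry quantitative meaning.

**What passing tests do and do not show.** The generator's trajectories
are reference-anchored and Gaussian with a single random intercept; real
cohorts have secular trends, informative missingness, measurement-device
mixtures, skewed analyte distributions beyond log-normal, and
puberty-timing heterogeneity that shifts individual velocity curves, none
of which are emulated. Recovery of planted effects demonstrates that the
pipeline's estimators are unbiased and correctly calibrated under the
model's assumptions — not that those assumptions hold in any particular
registry. The null profile (all offsets 0, ratios and multipliers 1,
γ ≡ 0) is an exact A/A configuration used to verify type-I error control;
the A/A check uses a single pooled height-SDS comparison per run, so its
clean-run rate is governed by one familywise level.

Everything is deterministic given the seed; regeneration with the same
seed and configuration is byte-identical, and every output directory
records the resolved configuration, the seed and a profile hash.

## Problem sizes

Validation runs use ~4000 children per stratum per sex for the
height/velocity recovery, 1500 per stratum for the endocrine recovery,
6000 normal-weight children for cross-lag recovery, 10,000 points for
centile-fit recovery and coverage, and 20 seeds × 800 per stratum for
null calibration — sizes at which Monte-Carlo error is a fraction of each
recovery tolerance while a full validation pass stays under a minute.

## Known limitations

- The LMS fitter estimates L freely; on data where L is weakly identified
  (small samples, near-constant CV) the L curve can wander at the age
  boundaries. M and S, and hence central centiles, are robust to this.
- The random-intercept model covers compound symmetry only — no serial
  correlation, random slopes, or crossed effects.
- Cross-lag estimates mix within- and between-stratum variation when
  strata with very different BMI means are pooled; interpret pooled
  coefficients accordingly or estimate within stratum.
- The Wald test in the piecewise model ignores the uncertainty of θ̂;
  at a few hundred subjects this is a percent-level effect on type-I
  error (measured ~5% at the default sizes).
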