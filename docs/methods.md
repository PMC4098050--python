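# Methods

## The statistical model

The diastolic left-ventricular posterior wall thickness (LVPWd) of healthy
adults is, by clinical convention, confined to 6–11 mm.  We therefore model it
as a doubly bounded continuous variable: the measurement `y` (mm) is mapped to
the unit interval, `y' = (y − a)/(b − a)` with `(a, b) = (6, 11)`, and `y'` is
assumed beta-distributed in the mean/precision parameterization

```
f(y'; μ, φ) = Γ(φ) / (Γ(μφ) Γ((1−μ)φ)) · y'^{μφ−1} (1−y')^{(1−μ)φ−1},
```

with mean `μ ∈ (0,1)` and precision `φ > 0`; the variance is
`μ(1−μ)/(1+φ)`.  Note the normalizing constant: a frequently mistyped form of
this density shows `Γ(μ)` in the numerator, which does not normalize; the
package implements the standard `Γ(φ)` constant (Ferrari & Cribari-Neto
reparameterization).

Both parameters carry their own regression:

```
logit(μᵢ) = xᵢᵀβ,        log(φᵢ) = zᵢᵀγ,
```

the *variable-dispersion* beta regression (VDBRM).  Covariates are used raw
(age in years, BSA in m², sex coded 1 = male); candidate terms are the linear
effects plus pairwise interactions, in both submodels.

### Estimation

Plain maximum likelihood: BFGS with the analytic gradient, from a
deterministic start (least squares of `logit(y')` on the mean design; the
precision intercept from a method-of-moments `φ` estimate, other `γ` at 0).
Convergence requires gradient max-norm below 1e−6 (500 iterations max);
the coefficient covariance is the inverse observed information (central
finite differences of the analytic gradient).  A fit whose maximum `φ`
exceeds 1e8 is flagged unconverged rather than returned silently — that is
the bounded-response analogue of separation.  Bias-reduced ML (as in the R
`betareg` package) is *not* implemented; at the sample sizes used throughout
(n ≥ 1000) the bias correction is negligible, and the test suite
cross-checks coefficients, standard errors and log-likelihood against
statsmodels' independent `BetaModel` implementation.

### Model selection and diagnostics

Backward elimination: at each step every removable term (interaction terms
shield their parent main effects) is dropped in turn and tested with the
likelihood-ratio test; the least significant term is removed while its
p-value exceeds α = 0.05.  Ties (to 1e−12) remove precision-submodel terms
first, steering selection toward a simpler dispersion structure.

Fit quality is the pseudo-R²: the squared sample correlation between the
fitted mean linear predictor and `logit(y')` (zero by convention for an
intercept-only mean submodel).  Diagnostics: Pearson residuals standardized
by `sqrt(μ(1−μ)/(1+φ))`, generalized leverage `∂μ̂ᵢ/∂yᵢ` through the observed
information, and Cook's distance via the Fisher-weighted mean-submodel hat
matrix.  The generalized-leverage trace approximates the parameter count
when responses stay well inside the bounds; with substantial probability
mass near a bound the trace inflates by ~15%, which is why the numerical
trace check runs on a generator whose law is interior.

## Published coefficient sets and the sampler

Four fitted models are registered (Polish / UHZ cohorts × {age, sex} /
{BSA, sex} predictors) with their printed point estimates.  Conditional
percentile curves invert the regularized incomplete beta function at the
covariate-specific shapes `(μφ, (1−μ)φ)` and map back to mm; random LVPWd
values are inverse-CDF draws (uniform variates through the beta quantile),
so every value lies strictly inside (6, 11) mm and sequences are reproducible
from the seed.  Covariates outside the observed clinical ranges (age 18–80,
BSA 1.28–2.73 m²) trigger a warning, not an error.  The legacy Sjögren
(age-sex) and Henry (BSA/weight) linear equations are kept for comparison;
they are *mean-only* and unbounded — the Sjögren female equation exceeds
11 mm at high age, which is exactly the argument for the bounded model.

## Synthetic cohorts

No individual-level clinical records are public, so cohorts are synthesized
from the published per-sex summaries (sample size, age and BSA mean/SD/range,
for the Polish and UHZ data sets).  Choices, in decreasing order of
consequence:

* **Truncated normal demographics, moment-matched.**  The distribution family
  is not published; we use a normal truncated to the published range whose
  parent parameters are solved so the *truncated* law has the published mean
  and SD (naive parameterization would shift the Polish male age mean by
  ~2 years).
* **Age ⟂ BSA.**  The joint law is unknown; independence is assumed.
* **Height/weight are bookkeeping.**  BSA is the modelled quantity; height is
  drawn per sex (1.78/1.65 m, SD 0.07) and weight back-solved through the
  DuBois formula, redrawing heights until BMI lands in the physiological
  16–35 window.  Downstream statistics never use height or weight.
* **LVPWd from the registry model** at each subject's own covariates, via the
  bounded sampler — so a generated cohort is, by construction, a draw from a
  known VDBRM and fitting it back is a full parameter-recovery test.

Screening reproduces the clinical inclusion rules (LVPWd 6–11 mm, age ≥ 18,
BMI 16–35), labelling each rejection with its first failed criterion; an
optional strict-interior mode excludes values exactly on a bound, which carry
no likelihood.  What the generator does **not** emulate: measurement/operator
error, between-center effects, and any age-BSA correlation — passing tests
say the statistical machinery is correct, not that real cohorts look like
this in those respects.

## The fiber model

A 1D monodomain cable, `∂V/∂t = D ∂²V/∂x² − I_ion/C_m`, discretized with
central differences and no-flux ends.  The string length *is* the LVPWd;
composition is 50% endocardial, 30% midmyocardial, 20% epicardial cells in
contiguous segments (segment sizes round the fractions, the epicardial
segment absorbing the remainder), paced at the endocardial end (~0.5 mm,
1 ms, twice-threshold amplitude).

**Numerics.**  dx = 0.1 mm, D = 0.00154 cm²/ms (the standard value for this
cell model, conduction ≈ 70 cm/s), dt = 0.015 ms — chosen so the explicit
diffusion stability bound `dx²/(2D) = 0.0325 ms` is met with a safety factor
above 2.  Hodgkin–Huxley gates advance by Rush–Larsen exponential steps
(exact for frozen rates and unconditionally stable); membrane potential and
concentrations by forward Euler.  |V| > 200 mV raises a stability error
naming dt/dx.  Nine cycles are simulated (≥ 8 conditioning beats); the final
cycle is recorded at 1 ms resolution.

**Cell kinetics.**  The detailed model is the ten Tusscher–Panfilov 2006
human left-ventricular cardiomyocyte (full current set; endo/mid/epi variants
via G_to and G_Ks).  Plasma K⁺/Na⁺/Ca²⁺ set the extracellular concentrations;
cell volume and capacitance scale the current-to-concentration factors
relative to the model's reference morphometry (185 pF / 16404 μm³), with SR
and subspace volumes scaling proportionally.

**Population physiology.**  Six parameters (plasma K⁺, Na⁺, Ca²⁺, cell
volume, stimulation period, capacitance) are sampled per virtual individual
from truncated normals at ±3 SD around the population means with a positivity
floor at 10% of the mean; cell volume — whose SD exceeds half its mean — uses
a log-normal matched to the same mean/SD.

**Pseudo-ECG and intervals.**  The unipolar extracellular potential
`Φ(t) ∝ ∫ (−∂V/∂x) ∂(1/r)/∂x dx` is evaluated at an axial electrode 20 mm
beyond the epicardial end (Gima–Rudy construction).  QT runs from the
stimulus of the measured beat to T-end by the tangent method: the steepest
terminal slope of the last significant T-deflection (≥ 30% of the post-QRS
maximum, either polarity — a transmural T wave can be multiphasic),
intersected with the isoelectric baseline (mean of the final 50 ms).
QTcF = QT/(RR/1000)^{1/3}, with RR = the individual's own stimulation period.
Drug action is Hill-equation I_Kr block, `C^N/(C^N + IC50^N)`, scaling the
I_Kr conductance by (1 − block); at 15 μM with IC50 9.64 μM and N = 1 the
block is 0.609.

**The two-current surrogate.**  Population runs (hundreds of fiber
simulations) use a Mitchell–Schaeffer-type two-current membrane model whose
closing time constant τ_close carries everything that matters at the
population level: transmural heterogeneity (205/190/175 ms endo/mid/epi — a
monotone gradient, so repolarization is a single epi→endo front and the T
wave is clean and upright; M-cell kinetics live only in the detailed model),
plasma-K sensitivity (τ_close ∝ (K_ref/K)^0.2, the physiological direction:
hyperkalemia shortens repolarization), and drug response
(τ_close × (1 + 0.11·block), the gain fixed once by matching the detailed
fiber's relative QT prolongation, ΔQT/QT = 0.065 at 60.9% block).  The
surrogate is a first-class reduced model, selected per run; it is not a
stand-in for anything missing.

## Scenarios

Sixty virtual individuals (30 per sex) are simulated under three string-length
assignments — constant (the pooled clinical mean, 8.3 mm, the sample-size-
weighted average of the four cohort-by-sex group means), the legacy Sjögren
equations, and random draws from the Polish age-sex VDBRM — each with and
without 15 μM of the I_Kr blocker.  One physiology draw per individual is
reused across every scenario and drug arm, so contrasts isolate the
wall-thickness rule and the drug; ΔQTcF is computed per individual before
summarizing (mean/SD, n−1 denominator, per sex and pooled).

Two degrees of freedom are not pinned down by any published number and are
documented defaults: the virtual individuals' ages (uniform 20–60 per sex)
and the spread added to the mean-only Sjögren equations (normal, SD 1 mm).
Published scenario summaries are therefore reproducible only at the property
level (drug prolongs QTcF in every individual; longer strings prolong QT;
the constant-length scenario has zero length-SD and the tightest baseline-QT
spread), not in exact figures — the upstream simulation platform's internal
settings (conditioning protocol, discretization, T-end rule, covariate
models) are unpublished.  One published inconsistency is deliberate: the
printed Sjögren equations give ~8 mm strings at mid-adult ages, while the
reference scenario summary reports 13 mm; this implementation follows the
printed equations.

## Problem sizes used in the test suite

Parameter-recovery and selection tests use n = 5000 synthetic subjects;
the LRT size check uses 500 replicates of n = 500; sampler checks use 10⁵
draws; population simulation properties run the full 60-individual, three-
scenario design with the surrogate kinetics, and detailed-model tests use
single cells or short coarse fibers with 2–3 conditioning beats.

## Known limitations

* 1D posterior-wall string only; no 3D geometry or torso ECG.
* Wild-type channels only; no genetic variants.
* The surrogate has no explicit Na⁺/Ca²⁺ dependence (both enter the detailed
  model only).
* Plain ML, not bias-reduced ML; small-sample coefficient bias is untested.
* The pseudo-R² of a fit on synthetic data brackets, but need not equal, the
  value reported for the clinical fit (~0.19), since the synthetic covariate
  law is itself a modelling choice.
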