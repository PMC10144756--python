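# Methods

This note documents the models, conventions and design choices behind
`postlrs`: what each computation assumes, which knobs matter, what the
synthetic cohorts do and do not emulate, and where the design was genuinely
open.

## 1. Prediction-error back-calculation

The unit of analysis is the refractive **prediction error** of a method on a
pseudophakic eye,

PE = SE_post − SE_pred,

where SE_pred is the spectacle-plane spherical equivalent the method predicts
for the IOL power actually implanted.  All refractions are spectacle-plane at
a 12 mm vertex; corneal-plane values are converted internally and never
exposed.  Positive PE is a hyperopic surprise.

### Base formulas

Three vergence formulas are implemented in closed form
(`postlrs.formulas`); each is a linear-fractional function of IOL power, so
predicted refraction at a given power and the power achieving a target
refraction are exact algebraic inverses (the inversion identity is tested to
1e-6 D over a 200-eye grid, and the closed forms are checked against an
independent numerical vergence-propagation oracle to 1e-9 D).

* **SRK/T** — corneal radius r = 337.5/K, corrected axial length
  LCOR = −3.446 + 1.716·AL − 0.0237·AL² above 24.2 mm, corneal width and
  height regressions, ELP = H + (0.62467·A − 68.747) − 3.336, optical axial
  length AL + (0.65696 − 0.02029·AL), indices 1.336 / 1.333.  The corrected-AL
  slope 1.716 is used because only it makes the two LCOR branches join at
  24.2 mm (with 1.715 the prediction jumps 0.011 D there); a residual step of
  ~2e-4 D remains and is inherited from the published regression.  The
  corneal-height square root is clamped at zero outside its domain.
* **Holladay 1** — anatomical ACD from the AG chord (AG = AL·12.5/23.45
  capped at 13.5 mm), ELP = aACD + SF with SF = 0.5663·A − 65.60, optical
  axial length AL + 0.2, corneal index 4/3.
* **Shammas-PL** — post-LASIK thin-lens formula: adjusted axial length
  0.9·AL + 2.3, ELP = pACD + 0.05 with pACD = 0.5835·A − 64.40, corneal
  vergence 1/(1.0125/Kc), corrected keratometry Kc = 1.14·K − 6.8 (the
  clinically-derived correction; its fixed point is at K ≈ 48.57 D, so every
  post-myopic-LRS cornea maps lower).

A single A-constant parameterizes all internal methods; it is converted to
each base formula's native constant by the standard linear relations above.
A useful verified direction: predicted SE is strictly *increasing* in the
A-constant at fixed implanted power (a larger constant means a deeper ELP,
hence more required power, hence a more hyperopic prediction) and strictly
decreasing in implanted power.

### No-history corrections

Each method transforms the measured biometry and/or adds an IOL-power offset
before its base formula; every coefficient lives in the
`postlrs.formulas.COEFFS` registry and is locked by tests.  Ferrara's
AL-dependent keratometric index (n = −0.0006·AL² + 0.0213·AL + 1.1572) and
the R-factor radius scaling used as ALMA's core
(r′ = r / (−0.0276·AL + 1.6512)) follow the published regressions.  The Kim
(keratometric-index rescaling, 1.3319/1.3375), Jin (Kc = 1.114·K − 6.062,
Holladay 1, aiming −0.75 D) and Latkany (power offset −(0.47·SE_est + 0.85)
with the pre-LRS spherical equivalent estimated from the measured K as
(K − 43.86)/0.8) corrections are this package's documented reconstructions of
those methods' published functional forms; the pipeline-level guarantees
(inversion, zeroing, range comparison, recommendation logic) do not depend on
their exact coefficients.  Jin's −0.75 D aim is a native target used for
power selection only — PE back-calculation always uses the predicted
refraction at the implanted power.

**Barrett True-K** has no public algebra and is served from an external
prediction table (eye_id, constant, predicted SE).  Tables with several
constants per eye are linearly interpolated, which lets the constant search
treat the method as continuous.  Synthetic cohorts use a clearly-labelled
surrogate (`synthetic_barrett_table`: SRK/T at rescaled K) that mimics the
interface, not the formula.

## 2. Constant optimization (zeroing-out)

Eyes are grouped per (IOL model × method); only known models with ≥ 3 eyes
are eligible (under-represented models make the zeroing unreliable), and
unknown-model eyes are excluded from optimization but retained in the
manufacturer-constant arm.  Within a group the constant solves ME(c) = 0 by
bracketed root-finding over [A − 6, A + 6] (widened once to ±12; post-LRS
constants can drift far, and a bounded two-stage bracket keeps failures
diagnosable), tolerance |ME| ≤ 1e-3 D — three printed decimals.  ME is
monotone in the constant, so the root is unique.  External tables are grid
searched at 0.01 steps (ties toward the smaller constant); a single-constant
table degrades to an additive refraction offset, flagged
`offset_optimized`.  Failed groups keep the manufacturer constant and are
flagged.  Optimization is deterministic.

Zeroing is *locally affine per eye*, not a uniform shift: each eye's PE moves
by its own sensitivity dSE/dA times the constant change, and sensitivities
vary with biometry (on the default cohort, per-eye shifts within one group
differ by up to ~0.25 D even though the group mean lands exactly on zero).
MedAE may go up or down under zeroing; only |ME| is guaranteed not to
increase.

## 3. Accuracy battery and tests

Per method/group: signed ME; MedAE, MAE, min, max, IQR of the absolute PEs
(type-7 quartiles); the standard error of the absolute errors and
CI95 = MAE ± 1.96·SE (the interval is around the MAE, matching how such
tables are conventionally printed); counts within ±0.50 / ±1.00 D, inclusive
(|PE| ≤ t, the conventional reading).

Inference (`postlrs.stats`): exact one-sample Kolmogorov–Smirnov normality
screen with estimated mean/sd (Lilliefors correction available as an
option); one-sample t of ME against zero; Friedman's test on absolute errors
with average ranks and tie correction, pairwise post hoc as rank-sum
z-comparisons Bonferroni-multiplied by k(k−1)/2 (the textbook default; the
post-hoc flavour is the one genuinely open choice here); Cochran's Q on the
threshold indicators with pairwise McNemar (no continuity correction —
exactly the 2-column Cochran Q) Bonferroni-adjusted.  Degenerate inputs:
fully tied Friedman rows give χ² = 0, p = 1; a Cochran matrix whose rows are
all constant has a zero denominator and raises.  Significance threshold 0.05
throughout.

### Repeated-measures power

`rm_sample_size` returns the smallest N whose achieved power reaches the
target for a one-group within-factor design with m measurements: numerator
df m − 1 (nominal), error df (N − 1)(m − 1)·ε (Greenhouse–Geisser), and
noncentrality λ = f²·N·m·ε.  The entered f derives from the partial η² of
the within-subject effect (f = √(η²/(1−η²))), which already embodies the
correlation among repeated measures, so the correlation parameter (default
0.5) is accepted for interface parity but does not enter λ.  Under this
convention the design with m = 7, η² = 0.206 (f = 0.509), α = 0.05, ε =
0.357 reaches 85 % power at N = 27 (power 0.843 at 26, 0.860 at 27); this
crossing is what fixed the convention among the candidates the noncentral-F
literature admits.

## 4. Range stratification

K and AL cutoffs are the quartiles of the optimizable subset rounded to the
nearest 1.00 D / 0.50 mm (half away from zero); coincident rounded cutoffs
raise.  The AL/K ratio uses fixed cutoffs 2/3 and 3/4.  All intervals are
(a, b] with unbounded outer ranges, so a boundary value falls in the lower
range.  Cutoffs are always derived from the optimizable subset and reused
for both arms, keeping the strata comparable.  Per range: full battery +
Friedman/Cochran, with tests skipped (warning) below 5 eyes.

LOESS trends use the classical tricube-weighted local polynomial (span 0.75,
degree 1 by default; degree 2 available) on a 100-point grid over the
observed range; the implementation is cross-checked against statsmodels'
lowess.  Constant data is reproduced to 1e-9 and linear data exactly at
degree 1.

## 5. Recommender

Two built-in 4×4 decision tables (manufacturer-constant and
optimized-constant arms) map (K range, AL range) to ALMA, Barrett True-K, or
the pair; three AL/K rows per arm act as tie-breaks.  AL/K rows are consulted
*only* for pair cells and never override a single-method cell (the tables do
not define any interaction for single-method cells, so none is invented).
An inconclusive tie-break keeps the pair and suggests the arithmetic mean of
the two methods' powers for the surgeon's target (default 0 D; a method's
native aim is overridden by the surgeon target at this layer).  In the
optimized table the flat-K/long-AL cells resolve to ALMA because AL/K always
exceeds 0.75 there.  The transcription is locked cell-for-cell against an
independently transcribed fixture (38 entries).  Recommendations are
research decision-support output, not clinical advice.

## 6. Synthetic cohorts

`simulate_cohort` draws (AL, K) from a correlation-coupled (ρ = −0.5)
bivariate normal truncated to the configured rectangles; the latent means
are recentered by a 2-D root-find on the Tallis moments of the truncated
distribution so the *observed* means equal the configured ones (the
correlation couples the two margins, so per-margin recentering is not
enough).  Truncation necessarily shrinks the spread below the latent sd.
Defaults: AL 27.65 ± 2.11 mm on [23.72, 34.20], K 38.08 ± 2.69 D on
[31.56, 43.81] — the descriptive statistics of the clinical setting the
pipeline targets.

IOL models come from a nine-model catalog with a small-share tail (so
cohort-sized draws contain sub-3 models), labelled A-constants near 118–119.5
and per-model true constants offset up to ±0.75 from the label (or supplied
explicitly); ~19 % of records lose their model label, exercising the
manufacturer/optimized split.  Implanted power is the truth method's power
for a random target in {0, −0.25, −0.5} D quantized to 0.5 D steps;
SE_post is the truth method's prediction at that power plus N(0, 0.4 D)
noise.  Because the outcome is generated at the quantized power, the
generating constant stays exactly identifiable: with zero noise, zeroing
recovers it to 1e-3, and the sidecar replays every noiseless refraction to
1e-9.  `truth_mixture_cohort` lets the generating method vary by (K, AL)
cell, which is how the range comparison's recovery property is tested (at
σ = 0.05 D and 60 eyes/range the generating method has the lowest MedAE in
every range).

What the simulator does **not** model: ablation-zone optics or topography
(the post-LRS measurement bias is represented implicitly by letting truth
methods disagree with naive formulas), biometer-specific error structure,
anything beyond additive Gaussian refraction noise, or literature-sourced
heterogeneity.  Passing recovery tests therefore demonstrates the
*pipeline's* correctness — grouping, zeroing, stratification, selection —
not the clinical superiority of any method on real eyes.

## 7. Problem sizes and numerical choices

Default driver/test sizes — 132-eye cohorts, 200-eye inversion grids,
5000-eye moment checks, 60 eyes per range for recovery — were chosen as the
smallest sizes at which each property is sharply decided; everything runs in
seconds on one core.  Tolerances: 1e-6 D inversion, 1e-3 D zeroing (with a
2e-3 D allowance on the per-eye affine check for curvature in the constant),
1e-9 D sidecar replay.  Ties: quartile rounding is half-away-from-zero;
external-constant grid ties go to the smaller constant; range boundaries go
to the lower range.

## 8. Known limitations

* Barrett True-K is interface-only; any "Barrett" numbers produced from the
  synthetic surrogate characterize the surrogate, not the real formula.
* The Kim/Jin/Latkany correction coefficients are documented
  reconstructions (Section 1); swap in verified coefficients via `COEFFS`
  before drawing method-level clinical conclusions.
* Constant zeroing on atypical eyes is debated in the field; the package
  takes no position and simply provides both arms.
* The recommender's decision tables are fixed inputs; re-deriving them from
  new data is out of scope.
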