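# postlrs

Evaluation pipeline for **no-history IOL power calculation after myopic laser
refractive surgery (LRS)**.

After myopic LASIK/PRK/LASEK, keratometers overestimate central corneal power
and standard IOL formulas misplace the effective lens position, producing the
well-known *hyperopic surprise* after cataract surgery.  "No-history" methods
correct for this without any pre-refractive-surgery data.  This package
implements the back-calculation study design used to compare such methods on
a pseudophakic cohort, and — because real post-LRS cohorts are scarce — a
synthetic cohort generator with the right statistical structure so every
stage is testable end to end.

It is aimed at researchers in ophthalmic biometry / clinical optics who want
a reproducible, scriptable version of this analysis rather than a spreadsheet.

## What it computes

For each eye (axial length `AL`, mean keratometry `K`, implanted IOL power
`P`, labelled A-constant, postoperative spherical equivalent `SE_post`) and
each method `m`, the engine back-calculates the refraction the method would
have predicted for the implanted lens, and the **prediction error**

```
PE = SE_post − SE_pred(m; AL, K, P, constant)      (D, spectacle plane, 12 mm vertex)
```

with PE > 0 a hyperopic surprise.  Methods implemented:

| method | base formula | correction |
|---|---|---|
| ALMA | SRK/T | AL-dependent corneal-radius scaling (R factor) |
| Barrett True-K | external | passthrough table (formula unpublished) |
| Ferrara | SRK/T | AL-dependent variable keratometric index |
| Jin | Holladay 1 | linear corrected-K regression, aims −0.75 D |
| Kim | SRK/T | adjusted keratometric index |
| Latkany (flat-K) | SRK/T | IOL-power offset from estimated ablation |
| Shammas c.d. | Shammas-PL | Kc = 1.14·K − 6.8 |

On top of the engine:

* **constant optimization** — per (IOL model × method) group of ≥ 3 eyes, the
  lens constant is adjusted until the mean signed PE is zero ("zeroing-out"),
  removing systematic bias so formulas are comparable;
* the standard **accuracy battery** (ME, MedAE, MAE, IQR, CI, % of eyes
  within ±0.50 / ±1.00 D) with Friedman + Bonferroni and Cochran Q tests;
* **range-partitioned comparison** over quartile-derived K and AL cutoffs and
  the AL/K ratio (cutoffs 0.67, 0.75), with LOESS trend curves of PE;
* a **multi-formula recommender**: a (K range × AL range) decision table with
  AL/K tie-break and power averaging for unresolved pairs;
* a **noncentral-F power module** for the within-factor repeated-measures
  design (Cohen's f from partial η², Greenhouse–Geisser ε).

## Worked example

```python
from postlrs import EyeRecord, Method, predict, emmetropic_power

eye = EyeRecord("case1", al=27.44, k=38.34, a_const=118.4,
                iol_model="SN60WF", p_iol=18.0, se_post=-0.50)

cell = predict(Method.SHAMMAS, eye, eye.a_const)
print(f"Shammas predicted SE: {cell.se_pred:+.2f} D")
print(f"prediction error:     {eye.se_post - cell.se_pred:+.2f} D")
print(f"emmetropic power:     {emmetropic_power(Method.SHAMMAS, eye, eye.a_const):.2f} D")
```

prints

```
Shammas predicted SE: +0.12 D
prediction error:     -0.62 D
emmetropic power:     18.16 D
```

i.e. for this long, flattened eye the Shammas chain predicts +0.12 D with the
implanted 18.0 D lens; the observed −0.50 D gives a −0.62 D (myopic)
prediction error, and an 18.16 D lens would have targeted emmetropia under
the method.

## The analysis pipeline

Numbered drivers under `analysis/` run the full study on a synthetic cohort
and write their tables under `results/`:

```
python analysis/01_simulate_cohort.py        # 132-eye cohort + truth sidecar
python analysis/02_optimize_constants.py     # per-model constant zeroing
python analysis/03_formula_accuracy.py       # whole-cohort battery + tests
python analysis/04_range_analysis.py         # K / AL / AL-K ranges, LOESS
python analysis/05_recommendations.py        # per-eye decision-table output
```

The generator's defaults encode the cohort structure the analysis assumes
(AL 27.65 ± 2.11 mm on 23.72–34.20, K 38.08 ± 2.69 D on 31.56–43.81,
AL–K correlation −0.5, ~19 % unknown IOL model, 0.4 D refraction noise); see
`docs/methods.md` for every choice and its rationale.

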