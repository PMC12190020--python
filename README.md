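# cuprackit

Chemometric analysis and validation for microplate **CUPRAC** (cupric ion
reducing antioxidant capacity) assays.

The CUPRAC assay measures the total antioxidant capacity of a sample: the
antioxidants reduce a Cu(II)–neocuproine reagent to an orange Cu(I) complex
whose absorbance at 450 nm is read in a 96-well plate. Results are expressed
as Trolox equivalents (TEAC, mol Trolox per gram of sample). Because Trolox
dissolves poorly in water, the solvent used to prepare standards and
extracts materially changes the signal — so an assay lab needs to (i) find
the solvent blend that maximises the signal, (ii) validate the Trolox
calibration under that blend, (iii) quantify samples, and (iv) compare
samples statistically. `cuprackit` implements that entire workflow on plain
CSV inputs, for analytical chemists validating or running the assay.

## Models and statistics

**Solvent optimization.** Compositions of methanol/ethanol/water
(volume fractions `z1 + z2 + z3 = 1`) are screened in a simplex-lattice
design (3 vertices, 3 edge midpoints, centroid; triplicate signals ψ in AU).
Each composition class (pure / binary / ternary) gets an average replicate
standard deviation σ<sub>average</sub>; signals are transformed as
Φ = ψ·σ<sub>average</sub> and the quadratic Scheffé canonical polynomial

&nbsp;&nbsp;Φ = k₁z₁ + k₂z₂ + k₃z₃ + k₁₂z₁z₂ + k₁₃z₁z₃ + k₂₃z₂z₃

is fitted by ordinary least squares. Prediction divides back by the
σ<sub>average</sub> of the candidate composition's own class; the optimizer
scans the simplex lattice plus all closed-form stationary points
(interior and per-edge) and returns the composition maximising the
predicted absorbance.

**Calibration validation (ICH-style).** For the Trolox line y = φx + β:
Pearson r; lack-of-fit vs pure-error ANOVA with a one-sided F test
(F<sub>exp</sub> = MS<sub>LoF</sub>/MS<sub>pure</sub>, linear iff
r > 0.990 and F<sub>exp</sub> < F<sub>crit</sub>); LOD = 3.3·σ<sub>blank</sub>/φ
and LOQ = 10·σ<sub>blank</sub>/φ; per-point back-calculated accuracy
(±15% acceptance); kinetic precision CV = 100·σ/μ; and the molar
absorptivity ε = φ·10⁶/h (Beer–Lambert, path length h in cm).

**Quantification.** TEAC = ΔA·V_f·V_i / (ε·V_s·W_s·h), with ΔA the
blank-corrected endpoint absorbance and the V/W terms the assay geometry.

**Group comparison.** Cochran's C variance-homogeneity test, one-way ANOVA
(computable from n/mean/SD summaries alone), and a multiple-range test
(Fisher LSD by default, Tukey optional) yielding homogeneous subsets.

## Worked example

The package bundles two reference datasets: the seven-composition solvent
screen and a six-level triplicate Trolox calibration (0–50 µM).

```python
import cuprackit as ck
from cuprackit.datasets import load_solvent_screen, load_trolox_calibration

res = ck.ScheffeMixtureModel(load_solvent_screen()).fit()
print(res.summary())
opt = res.optimize(grid_step=0.005)
```

```text
Quadratic Scheffé mixture model (transformed signal Phi)
  observations: 21    residual SS: 7.052e-05
  sigma_average: binary=0.046, pure=0.039, ternary=0.061
  term                    coef   std err
  k1 (methanol)          0.046     0.001
  k2 (ethanol)           0.038     0.001
  k3 (water)             0.015     0.001
  k12 (MeOH:EtOH)        0.063     0.006
  k13 (MeOH:water)       0.112     0.006
  k23 (EtOH:water)       0.065     0.006
optimum: methanol 0.64 / ethanol 0.00 / water 0.36 -> predicted 1.326 AU
```

The methanol–water interaction (k₁₃ = 0.112) dominates the blend effects,
and the best solvent is methanol:water 0.64:0.36 with a predicted maximum
absorbance of ≈1.33 AU — roughly 3.4× the pure-water signal, reflecting
Trolox's poor aqueous solubility.

```python
cal = ck.TroloxCalibration.from_dataframe(load_trolox_calibration()).fit()
print(cal.summary())
```

```text
Trolox calibration (OLS)
  y = 0.013 x + 0.039   (n = 18, r = 0.998)
  slope SE 2.11e-04   intercept SE 6.40e-03
  lack-of-fit ANOVA:
    pure error  SS 1.841e-03  df 12
    lack-of-fit SS 1.912e-03  df 4
    F_exp 3.1147  vs  F_crit(0.05) 3.2592
  linear: True (r > 0.99: True; F_exp < F_crit: True)
```

The line is linear over 0–50 µM (r = 0.998, F<sub>exp</sub> < 3.2592 on
(4, 12) df). `cal.validate(path_length_cm=0.5)` adds LOD 0.82 µM,
LOQ 2.47 µM (from the three blank replicates) and
ε = 2.60×10⁴ ± 0.04×10⁴ L mol⁻¹ cm⁻¹.

Comparing three feed-ingredient TEAC summaries (mmol/g):

```python
gs = [ck.GroupSummary("A", 3, 68.6, 2.9),
      ck.GroupSummary("B", 3, 62.2, 2.7),
      ck.GroupSummary("C", 3, 71.7, 3.1)]
print(ck.AntioxidantComparison(gs).fit().summary())
```

```text
TEAC group comparison
  B: 62.2 +/- 2.7 (n=3)
  A: 68.6 +/- 2.9 (n=3)
  C: 71.7 +/- 3.1 (n=3)
  Cochran C = 0.380 (crit 0.871, alpha 0.05) -> homogeneous
  one-way F(2,6) = 8.346, p = 0.0185
  homogeneous subsets (lsd, alpha 0.05): {B}; {A, C}
```

Variances are homogeneous, the means differ overall (p ≈ 0.02), and the
range test separates ingredient B from the statistically comparable pair
A and C.

The same stages are available from the shell (`cuprackit optimize-solvent`,
`validate`, `quantify`, `compare`, `simulate`, `run`); see `cuprackit --help`.

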