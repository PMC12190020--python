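# Methods

This note documents the models, the numerical choices and the limits of
what the test suite demonstrates. It is the package's own account of its
science; all numbers quoted here are computed by the code in this
repository (the test suite or `scripts/acceptance.py`).

## Mixture model for solvent selection

The solvent screen is a seven-point simplex-lattice design on
methanol/ethanol/water volume fractions: three vertices, three edge
midpoints and the centroid, each with triplicate absorbance signals ψ (AU).

**Class sigmas and the signal transformation.** Compositions are classed
by the number of nonzero fractions (pure/binary/ternary, zero tolerance
1e-6 on normalised fractions). For each class, σ_average is the unweighted
mean over its compositions of the per-composition sample SD (n−1) of ψ.
On the bundled screen these are 0.0388 / 0.0457 / 0.0605 AU, printing as
0.039 / 0.046 / 0.060. The fitted response is the transformed signal
Φ = ψ·σ_average(class); predictions are divided back by the σ_average of
the *candidate* composition's own class. This back-transform is
deliberately class-wise: it reproduces the screen's validated optimum on
the methanol–water edge, where an interior composition has a higher Φ but
a lower ψ after division by the larger ternary σ. The resulting ψ surface
is discontinuous across class boundaries, which is why the optimizer never
relies on smoothness (next section).

**Fitting.** The six-term quadratic Scheffé polynomial is fitted by OLS to
all replicate observations (no intercept; the linear terms span the
constant on the simplex). The design matrix must have rank 6, i.e. contain
six independent support points; the error message lists missing canonical
support. Standard errors come from the usual OLS covariance. On a
saturated design the fit interpolates and equals the closed-form Scheffé
estimates k_i = Φ̄(vertex i), k_ij = 4Φ̄(edge ij) − 2(k_i + k_j); the test
suite asserts agreement to 1e-10, and that noise-free simulated screens
are recovered to machine precision.

**Composition handling.** Input fractions summing to 1 within 0.02 are
renormalised to exactly 1 (printed designs often give the centroid as
0.33/0.33/0.33); larger deviations are rejected. Coefficients are reported
at 3 decimals; JSON reports keep full precision.

**Optimization.** The optimizer evaluates the back-transformed ψ at every
simplex lattice point of pitch `grid_step` (default 0.005), at the three
vertices, at each edge's closed-form stationary point
t* = (k_i − k_j + k_ij)/(2·k_ij), and at the interior stationary point of
Φ restricted to the simplex plane (2×2 linear system). Exact ties break
toward larger methanol then larger water fraction. Because every class
stratum (vertices, edges, interior) is searched with its own closed-form
candidates, the class-wise discontinuity of ψ cannot hide a maximum; a
test asserts dominance over exhaustive grid search at pitch 0.01. On the
bundled screen the optimum is methanol:water = 0.64:0.36 (edge stationary
point at z1 = 0.639) with predicted ψ ≈ 1.326 AU.

Rounding note: fitting the 3-decimal bundled signals gives
k = (0.0461, 0.0382, 0.0150, 0.0633, 0.1117, 0.0652); with these, slightly
different third decimals (±0.001) are expected relative to analyses run on
unrounded instrument output, and the predicted maximum lands within ~1%
of analyses based on full-precision data.

## Calibration validation

OLS line with intercept on all replicates; Pearson r is reported signed
and compared to r_min = 0.990 directly (not r²). The lack-of-fit/pure-error
ANOVA uses SS_pure = Σ_levels Σ(y − ȳ_level)² with n − L df and
SS_lof = Σ_levels n_level(ȳ_level − ŷ_level)² with L − 2 df; the two sum
to the total residual SS about the line (asserted to 1e-10 relative). The
F test is one-sided with MS_lof in the numerator. On the bundled
calibration: y = 0.013x + 0.039, r = 0.998, F_exp = 3.115 on (4, 12) df
against F_crit(0.05) = 3.2592 — linear.

F critical values are computed through the inverse regularized incomplete
beta function (F and Beta quantiles are related by
w = I⁻¹(d1/2, d2/2; 1−α), F = d2·w/(d1(1−w))); a 12-entry fixture checks
4-decimal agreement with published tables, and an independent route through
`scipy.stats.f.ppf` is asserted equal.

**σ_blank and LOD/LOQ.** LOD/LOQ = 3.3 and 10 × σ_blank/φ. Two σ_blank
estimators are exposed and the choice is recorded in reports: the sample
SD of the blank (0 µM) replicates (default; 0.0032 AU here, giving
LOD 0.82 / LOQ 2.47 µM) and the regression residual SD. The estimators
can differ by tens of percent at n = 3 blanks, so reported LOD/LOQ values
are only comparable when the estimator is stated; the exact LOQ/LOD ratio
10/3.3 holds regardless.

**Accuracy and precision.** Back-calculated accuracy is
100·(x̂ − x)/x for x > 0; at the blank the percent form is undefined
(zero denominator), so the absolute deviation in µM is reported and
flagged as such. Precision CV pools all replicate × timepoint kinetic
readings per level; a zero mean yields NaN rather than a fabricated value.
Molar absorptivity ε = φ·10⁶/h converts the µM-based slope to
L mol⁻¹ cm⁻¹; its SE is the slope SE times the same factor
(ε = 2.60×10⁴ ± 0.04×10⁴ here at h = 0.5 cm).

**Endpoint rule.** Kinetic series reduce to a single absorbance as the
reading at the final timepoint by default (configurable to the mean of the
last N readings); the rule is logged because published single-absorbance
tables rarely state which of the monitored readings they use.

## TEAC quantification

TEAC = ΔA·V_f·V_i/(ε·V_s·W_s·h), computed and stored in mol/g; display
defaults to mmol/g (exact 10³ factors). Default geometry: V_f = 0.25 mL,
V_i = 10 mL, V_s = 0.10 mL, W_s = 0.080 g, h = 0.50 cm. Blank wells are
averaged to one blank endpoint; negative ΔA is allowed but flagged. A ΔA
above the validated linear range (default threshold 0.70 AU, the top
calibration signal) is reported with a warning, because a capacity
computed from an out-of-range signal inherits no validity from the
calibration; mmol/g-scale TEAC values at this geometry imply ΔA far above
the range, so the warning guards against silent unit or dilution errors.

## Group comparison

Cochran's C = max(s²)/Σs² with critical value
[1 + (k−1)/F(α/k; n−1, (k−1)(n−1))]⁻¹ (equal n required; the test is
undefined otherwise and the code refuses). One-way ANOVA is computed from
(n, mean, sd) summaries — SSB from means, SSW from SDs — so raw-replicate
and summary input give identical results (asserted to 1e-10, and against
`scipy.stats.f_oneway` as an independent oracle). The multiple-range test
is Fisher's LSD at α = 0.05 by default (the common default of commercial
DOE/statistics suites); Tukey HSD via studentized-range quantiles is the
conservative option. Groups are sorted by mean and merged into maximal
runs of mutually non-significant groups; subsets always cover all groups.
For summary input without an n column, n defaults to 3 and is recorded in
the report. Display p-values are floored at 1e-12.

On the reference ingredient summaries (B 62.2±2.7, A 68.6±2.9,
C 71.7±3.1 mmol/g, n=3): C = 0.380 (homogeneous), F(2,6) = 8.35
(p = 0.019), subsets {B} and {A, C}.

## Synthetic data

The generators emulate the screen and assay at their reference conditions:
mixture replicates ψ = Φ(z)/σ_class + N(0, σ_class) over the seven-point
design (a `mixture_noise_scale` factor scales the noise, 0 = noise-free);
calibration y = 0.013x + 0.039 + N(0, 0.004 AU) in triplicate over
0–50 µM; kinetic traces base + drift·t + N(0, 0.004); sample wells from
target TEAC values by inverting the TEAC formula, with per-replicate ΔA
noise `sample_sigma` defaulting to the photometric 0.004 AU. Default TEAC
targets are three samples in the ratio 68.6 : 62.2 : 71.7 scaled so the
largest ΔA is 0.65 AU, inside the validated range. Everything is
deterministic given the config seed.

What the generators do *not* emulate: plate edge/evaporation effects,
heteroscedastic or temporally correlated noise, extraction variability
beyond a single Gaussian ΔA term, and instrument drift nonlinearity.
Passing round-trip tests therefore demonstrate estimator correctness under
the assay's idealised noise model, not robustness to real-plate artifacts.

### Power limit of the three-ingredient subset pattern

One property test asks how often simulated three-ingredient experiments
(means in ratio 62.2 : 68.6 : 71.7, replicate CV matched to the reported
~4.3%, n = 3) reproduce the {B} vs {A, C} homogeneous-subset split. That
exact split cannot be highly probable at these effect sizes: it requires
the 6.4-unit A–B gap to test significant while the 3.1-unit A–C gap does
not, and the ratio of the two noncentralities is fixed at 6.4/3.1 ≈ 2.06
regardless of noise level or n. Maximising
P(reject at δ)·P(accept at δ/2.06) over δ bounds the joint rate near 0.6
even at infinite degrees of freedom; Monte Carlo at n = 3 peaks around
0.55 and gives ≈0.40–0.50 at the CV-matched noise. The observed split is,
in other words, a boundary outcome: informative when seen once, but not a
reproducible signature. The test asserts the 90% rate such a signature
would need and is expected to fail, documenting the limit rather than
hiding it.

## Problem sizes and numerical conventions

All analyses run on desk-scale data: 21 screen observations, 18
calibration points, 96-well plates. Simulation-based tests use 200 seeds
for recovery/pattern rates, 500 for slope unbiasedness and 2000 for ANOVA
type-I calibration — sizes at which the binomial noise on the asserted
rates is well inside the asserted bands. Tolerances: closed-form oracle
agreement 1e-10; machine-precision claims 1e-12; published-table F values
5e-5 (4 decimals); reproduction of 3-decimal reference coefficients to the
third decimal. Degenerate inputs are errors, not silent NaNs: singleton
compositions for σ estimation, unreplicated levels for pure error, zero σ
in a back-transform, unequal n for Cochran's C.

## Known limitations

* The class-wise back-transform makes predicted ψ discontinuous at class
  boundaries; predictions infinitesimally inside an edge differ from those
  on it. This mirrors how the transformation is defined, and is handled in
  optimization, but users interpolating the exported prediction grid
  should be aware of it.
* LOD/LOQ depend strongly on the σ_blank estimator at triplicate blanks.
* Cochran's C requires equal replicate counts; unbalanced designs need a
  different homogeneity test (out of scope).
* The LSD subset construction merges by runs in mean order; patterns in
  which a middle group is ambiguous produce overlapping subsets, as in
  standard multiple-range output, rather than a partition.
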