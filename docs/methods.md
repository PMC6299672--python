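# Methods

This note documents the models, conventions and design choices behind
`nirsfq`, in the order the pipeline runs them.

## Synthetic NIRS populations

The generator emulates a diffuse-reflectance FT-NIR campaign over a
population of ground, mesh-sieved lignocellulosic stem samples. Spectra are
log(1/R) absorbance on a uniform ascending grid spanning 4000–10,000 cm⁻¹
with 1557 points by default (the point count is the primary control; the
implied ~3.9 cm⁻¹ spacing is treated as nominal instrument resolution).

**Pure components.** Each of the five composition indicators (soluble
sugars, cellulose, hemicellulose, lignin, ash) receives 3–6 Gaussian
absorption bands with centers drawn inside the information-rich
4000–7500 cm⁻¹ window, widths of 10–60 cm⁻¹ and dimensionless
absorptivities of 0.004–0.02. The narrow widths reflect the narrow
combination/overtone features that make individual cell-wall polymers
distinguishable in this region; very broad bands would render the
components nearly collinear and the selection problem ill-posed. A water
component absorbs only inside 5150–5195 cm⁻¹ (the O–H combination band);
its per-sample amplitude is drawn independently of every modeling target,
so a sound variable selector should avoid that window. A sixth "matrix"
component represents the residual dry matter (extractives, protein,
pectin) and closes the composition: its concentration is
100 − Σ(five indicators). This compositional closure matters: real %-dry-
matter data are closed, which keeps the total absorbing mass of a sample
nearly constant. Without it the multiplicative-scatter-correction slope
becomes a chemical quantity, and dividing by it reduces the spectra to
ratio data from which absolute concentrations cannot be recovered by any
linear model.

**Mixing and nuisances.** Per sample,

    A(ν) = s · ( Σ_k c_k · ε_k(ν) + c_w · ε_w(ν) + b · ramp(ν) ) + o + e(ν)

with multiplicative scatter slope s ~ 1 + N(0, 0.02), additive offset
o ~ N(0, 0.01), linear baseline drift amplitude b ~ N(0, 0.005) and white
noise e ~ N(0, 2×10⁻⁴) AU. The noise level corresponds to a 64-scan-
averaged FT instrument; the scatter and drift amplitudes are set for
finely ground, sieved, dried powder in a fixed accessory — large enough
that skipping MSC or the derivative visibly hurts, small enough that the
corrected spectra retain the information a working assay of this type
demonstrably extracts (validation R² in the mid-0.9s for major
constituents). Larger settings make the synthetic task strictly harder
than the real one.

**Reference chemistry.** Concentrations are truncated normals (rejection
sampling, 1000 tries per draw, then an error): soluble sugars
18.2 ± 5.0, cellulose 28.3 ± 3.0, hemicellulose 14.0 ± 2.5, lignin
16.0 ± 2.5, ash 4.2 ± 1.0 % dry matter. Digestibility is linear-Gaussian
in the two recalcitrance drivers,

    total carbohydrates = 95 − 1.2·lignin − 0.8·ash + N(0, 2),

clipped to (0, 100]; hexose and pentose yields are the total plus
independent N(0, 2) offsets. With these defaults total-carbohydrate
yields land in roughly the 63–83 % window. The N(0, 2) coupling noise is
spectrally invisible, so ~30 % of digestibility variance is irreducible —
digestibility calibrations are expected to grade "fair", not "excellent",
which mirrors how such assays behave in practice.

**What the generator does not emulate.** Instrument line shape, detector
nonlinearity, wavelength miscalibration, moisture–matrix interactions,
and — importantly — measurement error in the reference chemistry itself.
Real wet-chemistry references carry 1–3 % relative error, which caps real
calibration statistics; synthetic references are exact, so the pipeline's
validation metrics on synthetic data run higher than a physical campaign
would produce. Passing tests therefore demonstrate correctness of the
algorithms and recoverability under the stated conditions, not expected
field performance.

## Preprocessing

Order of operations is MSC first, then the Savitzky–Golay first
derivative. MSC regresses each spectrum on a reference spectrum by OLS
(x ≈ a·r + b) and returns (x − b)/a; the reference is the **calibration-
subset mean**, which is then reused unchanged for validation spectra so no
validation information enters the transform. A spectrum whose fitted slope
is numerically zero is passed through unchanged and flagged. The SG filter
defaults to an 11-point window, 2nd-order polynomial, 1st derivative
(expressed per cm⁻¹), with polynomial refitting on truncated windows at
the edges; window and orders are configurable since instrument software
rarely reports them. PCA (mean-centered SVD, largest-|loading| element
forced positive) is provided for inspection only.

## Partitioning and outlier screening

Kennard–Stone ranks samples by max-min Euclidean distance on the
preprocessed spectra: the most distant pair first, then iteratively the
sample farthest from the selected set, ties to the lowest index. The first
⌈(1−f)·n⌉ ranked samples form the calibration subset (default f = 0.2, one
in five to validation). Because the modeling MSC reference must come from
the calibration subset but KS needs preprocessed distances, KS runs on
spectra preprocessed with the whole-population mean — a transform of X
only, involving no response values — and the modeling matrices are then
rebuilt with the calibration-subset reference.

Chauvenet's criterion flags a value when n·erfc(|z|/√2) < 0.5, with z from
the sample SD (n−1), in a single pass; a zero-SD vector flags nothing. The
campaign applies it per response to the calibration residuals of a
preliminary full-spectrum PLSR (configurable to raw reference values), and
flagged samples are dropped from that response's calibration only.

## Variable selection

Both selectors score a candidate subset by its cross-validated RMSE **at
the best component count up to the cap of 10** — the same rule the final
calibration uses. Scoring a 400-variable subset and a 4-variable subset at
a fixed large dimension would systematically penalize the larger one for
overfitting the cross-validation rather than for lacking information.

**CARS** (default 50 runs, 80 % Monte-Carlo sample ratio, leave-one-out
scoring): run i fits a PLS sub-model on a random sample subset over the
currently retained variables and ranks variables by |regression
coefficient|. The exponentially decreasing function r_i = a·e^(−k·i) with
a = (p/2)^(1/(N−1)), k = ln(p/2)/(N−1) forces the retained count from p
(run 1) to 2 (run N); after the EDF cut, adaptive reweighted sampling
draws p variables with replacement with probability proportional to
|coefficient| and keeps the distinct draws. The run with minimal RMSECV
wins; ties go to the smaller subset, then the earlier run. The latent
dimension of the weight fits is chosen once on the full spectrum by the
LOO rule — refitting sub-models at the raw cap makes the coefficient
ranking noisy enough to lose genuinely informative variables.

**Random frog** (default 10,000 iterations; 1,000 in the test suite as a
desk-scale setting, with 5-fold CV scoring): a reversible-jump-like chain
over subsets, started from Q = 2 random variables. Each iteration draws a
candidate dimension from round(N(|V|, 0.3·|V|)); shrinking keeps the
largest-|coefficient| members, growing samples ω = 3 times the deficit
from outside, fits, and keeps the best. Better candidates are always
accepted; worse ones with probability η·(RMSECV_cur/RMSECV_cand), η = 0.1.
Selection probability is chain-membership frequency; the subset is the
top 25 variables by probability (configurable, or a probability cutoff
with a top-5 fallback). A single 1,000-iteration chain can occasionally
fail to leave a noise-region start on 1557-variable spectra; the 10,000
default makes this rare.

## PLS conventions

NIPALS with mean centering only (no autoscaling of X or y). Regression
coefficients are reconstructed as B = W(PᵀW)⁻¹Qᵀ so predictions are
ŷ = ȳ + (X − X̄)B. Component choice: global minimizer of the LOO RMSECV
curve over 1..10, ties to fewer components.

Metric conventions, stated because they differ across the literature:

- RMSEC/RMSECV/RMSEP are √(SS/n) with no degrees-of-freedom correction.
- R²c and R²cv are 1 − SS_res/SS_tot against the calibration mean; R²cv
  can be negative and is reported as-is.
- **R²v is the squared Pearson correlation** between predicted and
  reference values on the validation set. Under biased predictions this
  differs from 1 − SS_res/SS_tot (a shifted prediction can have R²v = 1
  with nonzero RMSEP); both conventions are common, and the correlation
  form is the one this package reports for external validation.
- RPD = sample SD (n−1 denominator) of the validation reference / RMSEP;
  RER = reference range / RMSEP. RPD > 3 together with RER > 15 labels a
  calibration "excellent". A zero RMSEP reports infinite RPD/RER with a
  `perfect_fit` flag.

PLS-DA fits a multi-response model on one-hot class indicators (one column
per grade present in calibration); the predicted class is the argmax of
the predicted indicators, ties resolving to the earlier (better) grade
letter. R² is computed over the indicator matrix on calibration and Q² as
1 − PRESS/SS_tot on validation, both SS_tot against the calibration class
frequencies. A class present only in validation is predictable never and
counts as misclassification (with a warning).

## Grey relational scoring

Benefit indicators (soluble sugars, cellulose, hemicellulose,
total-carbohydrate yield) are normalized (x−min)/(max−min), cost
indicators (lignin, ash) as (max−x)/(max−min), so the ideal series is all
ones. Deng's coefficient ξ = (Δmin + ρΔmax)/(Δ + ρΔmax) uses the
conventional ρ = 0.5 (configurable; the choice shifts ξ levels but rarely
reorders samples). Weights: 0.5 on the chemical block split equally
(0.1 each) and 0.5 on total-carbohydrate digestibility — total
carbohydrates is the digestibility input because it is the quantity the
pretreatment-plus-hydrolysis assay summarizes. The grade
γ = Σ w_k ξ(k) is min-max rescaled to FQS ∈ [0, 100] so the best sample
scores exactly 100 (the mapping is anchored at both ends; an all-equal γ
vector maps to all-100 with a warning). Grade bands: A = [80, 100],
B = [60, 80), C = [40, 60), D = [20, 40), E = [0, 20) — closed below, and
A closed at 100.

## Campaign orchestration

`run_campaign` executes: simulate/load → preprocess → KS split → per
response {outlier screen → selection × {full, CARS, RF} → PLSR + metric
suite} → GRA scoring of the full reference table → PLS-DA on the
resulting grades × {full, CARS, RF}. Variable selection for the
classification variants uses FQS as the continuous selection response
(the grades are a discretization of it). All randomness flows from one
campaign seed through derived child seeds, so two runs with the same seed
serialize byte-identically; a failure in one response/variant combination
is recorded as an error row and the campaign continues. Reports are plain
CSV plus a YAML provenance block (seed, config hash, stage counts).

## Problem sizes

The test suite exercises the full 1557-variable grid with 60-sample
populations for recovery and selector-fidelity checks (random frog at the
1,000-iteration desk scale), 200-variable known-support designs for
selector benchmarking, and 30-sample / 120-variable campaigns for
determinism and orchestration tests. `scripts/acceptance.py` runs the
complete default campaign (60 samples × 1557 variables, 8 responses ×
3 spectra variants, 10,000 random-frog iterations).

## Known limitations

- Gaussian bands without instrument line shape or detector effects; band
  positions are random rather than assigned to real overtone chemistry.
- Digestibility is linear in lignin and ash only; real recalcitrance is
  nonlinear and multi-factor.
- Synthetic reference values are error-free, so calibration statistics on
  synthetic data exceed what physical reference chemistry permits.
- MSC assumes a constant additive offset; strongly curved baselines are
  only partially removed by the subsequent derivative.
- The random-frog chain is a stochastic optimizer: its selected subset is
  seed-dependent, and pathological chains, while rare at the default
  iteration count, are possible. The full-spectrum variant is always
  computed alongside as a control.
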