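# Methods

## Spin simulation

Spectra are computed by exact diagonalisation of the isotropic liquid-state
Hamiltonian H = Σᵢ νᵢIzᵢ + Σᵢ<ⱼ Jᵢⱼ(Iᵢ·Iⱼ) (Hz), with νᵢ = δᵢ × field(MHz)
measured from the 0.00 ppm TSP reference. Equivalent protons are expanded
into individual spin-½ nuclei; groups not coupled to anything are emitted as
analytic singlets, and the 2ⁿ-dimensional diagonalisation applies per
coupled component with a cap of 8 expanded spins — larger molecules are
split into subsystems in the library (glucose is two anomer C1-H/C2-H pairs
plus an uncoupled bulk ring envelope, since only the C1-H doublets and the
3.14–3.99 ppm bulk region are quantified at 60 MHz). Line intensities are
squared total-Ix matrix elements between eigenstates (equal-population,
high-temperature limit), normalised so the total intensity equals the total
proton count; lines below 10⁻⁶ proton-equivalents are pruned. Spectra are
sums of unit-area Lorentzians (default FWHM 0.55 Hz, the shimming target of
the benchtop protocol) on an ascending ppm grid with 5×10⁻⁴ ppm spacing.

Relaxation enters as a per-line steady-state saturation factor using the
T1 of the nearest spin group (Ernst expression; 1 − e^(−TR/T1) at the 90°
default). Per-line attribution by nearest group Larmor frequency is an
approximation that is exact for first-order multiplets and slightly blurred
for strongly coupled ones; it is adequate because T1 differences act at the
multiplet scale. Library T1 values are low-field estimates chosen so the
10 s repetition time satisfies the ≥5·T1 rule, except alanine, whose
strongly unequal T1s (1.51 s CH₃, 6.94 s α-CH) are the protocol's worked
example of T1-driven integral distortion.

### Water presaturation

Presaturation is a multiplicative retention factor
r(Δ) = 1 − exp(−(Δ/w)²) on each line, full suppression at the carrier.
A Gaussian dip was chosen over a Lorentzian one because the protocol's two
printed anchors cannot be met simultaneously by a Lorentzian profile: with
retention ≈0.42 at 60 Hz (the β-C1-H offset at 400 MHz), a Lorentzian's fat
tail still suppresses ~17% at 180 Hz (the α-C1-H offset), whereas the
observed α:β anomer distortion of 57:43 against the true 36:64 implies the
α resonance is nearly untouched. The Gaussian width is calibrated per
(field, power) setting: 18 Hz/0.42 fixes the 60 MHz / 58 dB width
(w ≈ 24.4 Hz), and the implied β/α retention ratio
(43/57)/(64/36) ≈ 0.424 fixes the 400 MHz / 50 dB width (w ≈ 81 Hz,
solved numerically). Other powers extrapolate the nearest anchor width by
10^(ΔdB/20); this amplitude-style mapping is an assumption, not a measured
law, and the anchors are exposed as configuration.

### Noise

Additive white Gaussian noise on the rendered spectrum with
σ = noise_sigma/√n_scans; the default per-scan σ gives a 64-scan spectral
noise of 2×10⁻³ intensity units, which puts the 8 mmol/L glucose standard's
flank-method SNR near 10–15 — the right order for a standard at the
quantification limit. Seeded generators are mandatory everywhere.

## Sample-preparation arithmetic

Recipes carry aliquot volumes and the TSP mass fraction. The final TSP
concentration is (%w/v ÷ 100) × V_TSP / (M × V_final): 264 µmol/L for the
biofluid recipe (450 + 50 + 50 µL) and 223 µmol/L for the calibration
recipe (500 + 50 + 50 + 50 µL), with M(TSP-d₄ sodium salt) = 172.26 g/mol.
The biofluid recipe also implies a 450/550 supernatant dilution applied to
cohort metabolite concentrations.

## Synthetic cohorts

Group statistics for 3-hydroxybutyrate, creatinine and glucose transcribe
the reported means ± SEM (SD = SEM·√n with the printed group sizes);
glucose in the diabetic group is detectable in a fraction 0.6 of samples
with 155 ± 56 mmol/L among detectable ones. Three generator choices matter:

- **Marginal distributions.** Positive-part truncated normal by default;
  when SD > mean (diabetic creatinine, marginally diabetic 3-HB), a
  zero-truncated normal cannot represent the CV and a moment-matched
  log-normal is used instead.
- **Urinary dilution.** Every sample's metabolites are scaled by a
  unit-mean log-normal factor (CV 0.5). Urine concentration varies several-
  fold with hydration — this is the reason creatinine normalisation exists —
  and omitting it makes synthetic cohorts unrealistically separable.
- **Severity coupling.** Disease markers co-vary through a one-factor
  Gaussian copula (glucose loading 0.9, ketone bodies 0.5–0.7, suppressed
  aromatics −0.3…−0.4). Marginals and detection fractions are preserved
  exactly; what changes is that the markers share a latent severity axis,
  as they do in patients. Glucose detectability is tied to the same latent,
  so the glucose-positive diabetics are also the metabolically extreme ones.
  "Non-detectable" diabetic glucose is drawn at 3 ± 2 mmol/L — below the
  8 mmol/L quantification limit but far above control levels — rather than
  set to zero.

Metabolites whose group means are not reported (acetone, acetate,
N-acetyls, lactate, methylsuccinate, formate, citrate, hippurate, indoxyl
sulphate) carry plausible urine levels flagged `anchored=False`; only their
direction of change between groups is meaningful, and the magnitudes are
deliberately modest (≈1.2–1.5×) so that the cohort's discrimination is
driven by the reported markers. Background glycine (0.9 mmol/L) and TMAO
(0.35 mmol/L) keep the bulk region non-empty.

The residual water signal is modelled as a post-suppression Lorentzian
(FWHM 10 Hz) at the presaturation frequency. Its area default is solved
analytically so that the water-overlap fraction of the α-C1-H bucket —
(blank water integral in the bucket)/(total bucket integral) — crosses the
10% criterion midway between 7.5 and 8.0 mmol/L total glucose, the
condition that makes the calibration report an 8.0 mmol/L LOQ.

The four-method comparison generator is multiplicative,
y = µ·bias·participant·noise, with method biases 0.929/0.820/0.988/1.287
(reproducing the reported per-method means around µ = 100 mmol/L), a
unit-mean participant factor of CV 1.0, and within-method CVs of 0.05 —
the last is a configuration value; no analytical CVs are reported.

## Preprocessing

Processing order is apodise → FT → phase → baseline → TSP-reference, and
is idempotent at its fixed point. Defaults: ×2 zero-filling to a power of
two with half-first-point correction; auto-phasing by Nelder–Mead over
(ph0, ph1) minimising total negative intensity from four starting phases;
asymmetric-least-squares baseline (λ = 10⁷, p = 10⁻³, 10 reweighting
iterations); referencing shifts the axis so the TSP maximum is exactly
0.00 ppm. The one-sided FT of a decaying exponential carries half the
absorption-mode area, so the FT is scaled by 2·dwell·field to make its
ppm-axis integral match the rendered-spectrum convention within
discretisation error (<2% round-trip).

## Quantification

Buckets are closed ppm intervals integrated trapezoidally on the native
grid with endpoint interpolation (adjacent buckets therefore sum exactly
to their union). **Integrals for quantification are taken after baseline
correction**: at 60 MHz the far Lorentzian tails of 100–600 mmol/L glucose
otherwise leak into the TSP reference window and visibly bend the
calibration. The water-overlap fraction is measured on raw spectra, since
baseline correction removes the broad water tail that defines the
criterion. SNR uses peak height after baseline correction over either the
mean |intensity| of 10 flanking points per side — sampled at the
instrument's digital resolution of ≈0.0026 ppm/point, not the simulation
grid — or the mean of the 10 largest points in the signal-free 9.0–9.5 ppm
region. LOD/LOQ are the lowest calibration concentrations reaching SNR 3
and 10; the LOQ additionally rises to the lowest concentration with water
overlap <10%. The overlap was interpreted as an area fraction (the
criterion's basis — height vs area — is not stated).

The shipped bucket table has 13 named metabolite windows (the 12 assigned
ones plus formate at 8.33–8.52 ppm) and 14 unanchored filler windows tiling
the remaining unexcluded 1.03–8.52 ppm span, for 27 total; the protocol's
exclusion regions (residual water 4.41–5.16 ppm and nine signal-free
spans) are built in, and the table refuses buckets that intersect them.
The exact bounds of the unnamed buckets are not reported; fillers are
flagged.

Creatinine normalisation carries a feasibility flag: when the Cn bucket's
bounds touch the 3.14–3.99 ppm glucose bulk envelope (as they must at
60 MHz), a warning is raised, reflecting the protocol's finding that Cn
normalisation is unreliable in high-glucose urine at this field.

## Chemometrics

Pipeline order is enforced by state tags on the feature matrix:
normalise (TSP or constant-sum) → exclusion filter → glog → Pareto →
model; wrong order raises. glog's λ defaults to the squared median
per-sample noise-bucket scale (λ is not reported). OPLS-DA is
orthogonal-signal-corrected PLS1 with one predictive component and a
configurable number of orthogonal ones (default 1; the number used in the
study is not stated). Its fitted Y with a orthogonal components equals the
(a+1)-component PLS1 solution, which the tests verify against an
independent PLS implementation. Q² = 1 − PRESS/TSS over stratified 10-fold
CV; permutation p = (1+#{perm ≥ obs})/(1+B). MCCV-SVM uses balanced
subsampling to the smaller class, 2/3 train splits, 100 repeats,
per-split feature ranking by |t| on training data only, and a linear SVM
(C = 1); split fraction, repeat count and ranking statistic are our fixed
choices. Classification runs on the transformed (glog/Pareto) matrix —
the dataset preparation described for the case study. Random forest uses
500 trees and 7 candidate variables per node with OOB validation.
Benjamini–Hochberg is the default multiplicity correction, Holm the
alternative. Varimax runs with Kaiser row normalisation, tolerance 10⁻⁸,
500 iterations max.

## Method agreement

For the balanced methods × participants design the ANOVA uses closed-form
sums of squares with methods fixed and participants random; the
participant variance component is (MS_P − MS_E)/a, truncated at zero with
a flag. Tukey HSD uses the studentised range on method means with the
two-way residual mean square as the error term. Agreement regressions are
ordinary least squares with t-based 95% CIs and coverage flags for slope 1
and intercept 0; OLS matches the style of gradient CIs reported, and the
replicate-averaged values are assumed as regression inputs. Deming
regression is a sensible alternative when both methods carry comparable
error, and can be layered on the same tables.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
cohorts of 10 + 14 samples on a 21 001-point axis, calibration series of
6–7 standards, 100-split MCCV, 10-fold CV, and 1000-replicate calibration
checks for CI coverage and FDR control; the acceptance script averages the
classification target over 20 independently seeded cohorts. Everything
completes in minutes on one CPU.

## Limitations

The simulator models a single Lorentzian linewidth — no shimming
artefacts, eddy currents, lineshape asymmetry, pH- or ionic-strength-
dependent shift drift, or radiation damping. The presaturation profile and
its power law are a calibrated phenomenological model, not a Bloch
simulation. T2 enters only through the fixed linewidth. The cohort
generator reproduces printed group statistics and plausible correlation
structure but not diet- or drug-derived signals, and spectra of real urine
contain many more minor metabolites; passing tests demonstrate that the
analysis pipeline recovers what the generator encodes, not that the
biological effect sizes generalise. 2D experiments, non-¹H nuclei and
vendor binary formats are out of scope.
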