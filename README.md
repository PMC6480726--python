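# benchnmr

Low-field (60 MHz) benchtop ¹H NMR spectrometers make urine metabolomics
possible outside the NMR facility — but at 60 MHz the spectrum is crowded,
water presaturation bleeds into nearby analyte signals, and multiplets span
6–7× more of the ppm axis than at 400 MHz. `benchnmr` implements, end to
end, a benchtop biofluid quantification and metabolomics protocol for this
regime, together with a physics-based synthetic spectrum/cohort generator so
that every stage can be exercised and validated without an instrument.

It is aimed at metabolomics researchers and methods developers who want a
tested, scriptable reference implementation of:

- **Spin simulation.** 1D spectra from exact diagonalisation of the
  isotropic spin Hamiltonian *H* = Σᵢ νᵢ *I*zᵢ + Σᵢ<ⱼ *J*ᵢⱼ (*Iᵢ·Iⱼ*), so
  second-order (strong-coupling) lineshapes at 60 MHz come out right;
  instrument effects as multiplicative factors — a Gaussian water-presaturation
  dip (calibrated so a signal 18 Hz from the 4.95 ppm carrier retains 42% of
  its intensity at the default 58 dB power), Ernst/steady-state T1 saturation
  (1 − e^(−TR/T1) at 90°), and √n SNR scaling with scans.
- **Quantification.** Trapezoidal bucket integration, internal-standard
  (TSP, 9 equivalent ¹H) normalisation, calibration lines with LOD/LOQ
  (3×/10× noise, plus a ≥10% residual-water-overlap criterion that fixes the
  total-glucose LOQ at 8.0 mmol/L), and the α-anomer → total glucose
  conversion factor 100/36 = 2.78 (α-glucose is 36% of the equilibrium
  mixture; only its C1-H doublet at 5.25 ppm is cleanly integrable at 60 MHz).
- **Chemometrics.** glog transform ln((x+√(x²+λ))/2), Pareto scaling,
  t-tests with Holm/FDR control, PCA with varimax rotation, OPLS-DA
  (orthogonal-signal-corrected PLS) with 10-fold Q², 2000-permutation
  testing, MCCV balanced-subsampling SVM ROC curves, and random-forest
  classification with out-of-bag validation.
- **Method agreement.** Two-way variance-components ANOVA
  (y*ᵢⱼ* = µ + M*ᵢ* + P*ⱼ* + e*ᵢⱼ*, methods fixed, participants random),
  Tukey HSD on method means, and pairwise agreement regressions with
  slope-covers-1 / intercept-covers-0 CI flags.
- **Synthetic cohorts.** Diabetic (n = 10) vs control (n = 14) urine
  cohorts whose group statistics transcribe the protocol's reported values
  (3-hydroxybutyrate 3.12 ± 0.99 vs 0.24 ± 0.06 mmol/L SEM; glucose
  detectable in 6/10 diabetics at 155 ± 56 mmol/L; creatinine 20.86 ± 10.56
  vs 6.30 ± 0.99 mmol/L), with per-sample urinary dilution and a latent
  disease-severity factor coupling the markers.

## Worked example

Simulate a noise-free 60 MHz glucose calibration series (100–600 mmol/L,
TSP internal standard 223 µmol/L), fit the calibration, and quantify an
unknown:

```python
from benchnmr.spin import AcquisitionConfig
from benchnmr import cohort, quantify
from benchnmr.preprocess import baseline_correct

config = AcquisitionConfig(noise_sigma=0.0)
concs = [100, 200, 300, 400, 500, 600]            # mmol/L total glucose
series = cohort.generate_calibration_series("glucose", concs, config, seed=0)
ratios = []
for spec in series:
    spec = baseline_correct(spec)
    alpha = quantify.integrate_bucket(spec, *quantify.ALPHA_C1H_BUCKET)
    tsp = quantify.integrate_bucket(spec, *quantify.TSP_BUCKET)
    ratios.append(quantify.tsp_normalize(alpha, tsp))
model = quantify.fit_calibration(concs, ratios)

tsp_mM = cohort.tsp_final_concentration(cohort.CALIBRATION_RECIPE) / 1000
theory = 0.36 / (tsp_mM * 9)   # anomer fraction × 1H, vs TSP × 9H
print(f"fitted slope      : {model.slope:.4f} per mmol/L (r = {model.r:.4f})")
print(f"theoretical slope : {theory:.4f} per mmol/L")
print(f"observed/predicted: {model.slope / theory:.2f}")
```

```
fitted slope      : 0.0743 per mmol/L (r = 1.0000)
theoretical slope : 0.1792 per mmol/L
observed/predicted: 0.41
```

The fitted slope is only ~42% of the slope predicted from the known
concentrations and proton counts: the water-presaturation pulse, only 18 Hz
away from the 5.25 ppm α-C1-H doublet at 60 MHz, suppresses the analyte
signal along with the water. Quantification through the fitted calibration
is unaffected by this attenuation, because the calibration itself absorbs it:

```python
sample, = cohort.generate_calibration_series("glucose", [155.0], config, seed=0)
ratio = quantify.tsp_normalize(...)
est, below_loq = quantify.quantify_from_calibration(ratio, model)
```

```
recovered         : 155.0 mmol/L (true 155.0)
alpha-anomer LOQ  : 2.88 mmol/L from total LOQ 8.0
anomer factor     : 2.78
```

The full case-study pipeline (cohort simulation → preprocessing →
bucketing → TSP normalisation → glog/Pareto → OPLS-DA, MCCV-SVM ROC and
random forest) runs as:

```bash
benchnmr run --seed 1 --out results/demo
```

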