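"""Synthetic calibration series, urine cohorts, and method-comparison tables.

This module stands in for the study's samples: it renders physics-based
60 MHz (or 400 MHz) spectra of glucose calibration standards and
diabetic/control urine cohorts whose group statistics transcribe the printed
protocol values, and emits four-method measurement tables with a
multiplicative bias/participant/noise structure.

Instrument effects applied per transition: water-presaturation attenuation
(Gaussian dip anchored at 42% retention 18 Hz from the 60 MHz carrier),
steady-state T1 saturation, additive white spectral noise with
σ = noise_sigma/√n_scans, plus a residual (post-suppression) water Lorentzian
at the presaturation frequency.  The residual-water area default is solved so
that the water-overlap fraction of the α-glucose C1-H bucket crosses the 10%
LOQ-determining threshold midway between 7.5 and 8.0 mmol/L total glucose,
the condition that fixes the protocol's 8.0 mmol/L LOQ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from . import library
from .quantify import integrate_bucket, ALPHA_C1H_BUCKET
from .spin import (AcquisitionConfig, Spectrum, TransitionList,
                   presat_attenuation, render_spectrum, t1_saturation_factor)

__all__ = [
    "PreparationRecipe",
    "BIOFLUID_RECIPE",
    "CALIBRATION_RECIPE",
    "tsp_final_concentration",
    "MetaboliteDistribution",
    "CohortSpec",
    "default_cohort_spec",
    "MethodComparisonSpec",
    "default_method_comparison_spec",
    "default_axis",
    "render_mixture",
    "generate_calibration_series",
    "generate_cohort",
    "generate_method_comparison",
    "WATER_LINEWIDTH_HZ",
    "default_water_residual_area",
]

TSP_MOLAR_MASS = 172.26  # g/mol, sodium 3-(trimethylsilyl)propionate-d4
WATER_LINEWIDTH_HZ = 10.0  # FWHM of the residual suppressed water hump


@dataclass(frozen=True)
class PreparationRecipe:
    """Aliquot bookkeeping for an NMR sample preparation.

    ``aliquots_uL`` maps component names to volumes; the TSP-carrying aliquot
    is named by ``tsp_aliquot``.  ``tsp_mass_fraction_pct`` is the % w/v TSP
    content of that aliquot (0.05 means 0.05 g per 100 mL).
    """

    aliquots_uL: tuple  # ((name, µL), ...)
    tsp_aliquot: str = "d2o_tsp"
    tsp_mass_fraction_pct: float = 0.05
    tsp_molar_mass: float = TSP_MOLAR_MASS

    def __post_init__(self):
        if any(v <= 0 for _, v in self.aliquots_uL):
            raise ValueError("aliquot volumes must be positive")
        names = [n for n, _ in self.aliquots_uL]
        if self.tsp_aliquot not in names:
            raise ValueError(f"recipe lacks the TSP aliquot {self.tsp_aliquot!r}")

    @property
    def final_volume_uL(self) -> float:
        return float(sum(v for _, v in self.aliquots_uL))

    @property
    def tsp_volume_uL(self) -> float:
        return float(dict(self.aliquots_uL)[self.tsp_aliquot])


#: 450 µL supernatant + 50 µL buffer + 50 µL ²H₂O/TSP → 550 µL final
BIOFLUID_RECIPE = PreparationRecipe(
    aliquots_uL=(("supernatant", 450.0), ("buffer", 50.0), ("d2o_tsp", 50.0)))

#: 500 µL analyte + 50 µL azide + 50 µL buffer + 50 µL ²H₂O/TSP → 650 µL
CALIBRATION_RECIPE = PreparationRecipe(
    aliquots_uL=(("analyte", 500.0), ("azide", 50.0), ("buffer", 50.0),
                 ("d2o_tsp", 50.0)))


def tsp_final_concentration(recipe: PreparationRecipe) -> float:
    """Final TSP concentration (µmol/L) from dilution bookkeeping.

    mass = (%w/v ÷ 100) g/mL × aliquot volume; concentration = mass /
    (molar mass × final volume).  The two protocol recipes give 264 and
    223 µmol/L.
    """
    V = recipe.final_volume_uL
    if V <= 0:
        raise ValueError("final volume must be positive")
    mass_g = recipe.tsp_mass_fraction_pct / 100.0 * recipe.tsp_volume_uL * 1e-3
    return mass_g / (recipe.tsp_molar_mass * V * 1e-6) * 1e6


# ---------------------------------------------------------------------------
# spectrum rendering with instrument effects

def default_axis(config: AcquisitionConfig, step_ppm: float = 5e-4) -> np.ndarray:
    return np.arange(config.sw_low_ppm, config.sw_high_ppm + step_ppm / 2,
                     step_ppm)


def _effective_transitions(concs: dict, config: AcquisitionConfig) -> TransitionList:
    """Concatenate metabolite transitions with T1 and presaturation factors."""
    parts = []
    presat_Hz = config.presat_ppm * config.field_MHz
    for name, conc in concs.items():
        if conc <= 0:
            continue
        for tl, t1s in library.metabolite_t1(name, config.field_MHz):
            sat = np.array([
                t1_saturation_factor(t, config.repetition_time_s,
                                     config.pulse_angle_deg) for t in t1s])
            fac = conc * sat[tl.group]
            if config.presat_enabled:
                fac = fac * presat_attenuation(
                    np.abs(tl.freq_Hz - presat_Hz), config.presat_power_dB,
                    config.field_MHz)
            parts.append(tl.scaled(fac))
    return TransitionList.concat(parts)


def _add_water(spectrum: Spectrum, config: AcquisitionConfig,
               area: float) -> None:
    if area <= 0:
        return
    gamma = 0.5 * WATER_LINEWIDTH_HZ / config.field_MHz
    spectrum.intensity = spectrum.intensity + area * (gamma / math.pi) / (
        (spectrum.ppm - config.presat_ppm) ** 2 + gamma ** 2)


@lru_cache(maxsize=16)
def default_water_residual_area(config: AcquisitionConfig = None) -> float:
    """Residual-water area making the α-C1-H water-overlap hit 10% at 7.75 mM.

    Solved analytically from A·F / (A·F + S) = 0.10, where F is the fraction
    of a unit-area residual-water Lorentzian falling inside the α-C1-H bucket
    and S the attenuated α-doublet bucket area of a 7.75 mmol/L total-glucose
    standard.
    """
    config = config or AcquisitionConfig()
    axis = default_axis(config)
    tl = _effective_transitions({"glucose": 7.75}, config)
    spec = render_spectrum(tl, axis, config.linewidth_Hz, config.field_MHz)
    lo, hi = ALPHA_C1H_BUCKET
    S = integrate_bucket(spec, lo, hi)
    gamma = 0.5 * WATER_LINEWIDTH_HZ / config.field_MHz
    F = (math.atan((hi - config.presat_ppm) / gamma)
         - math.atan((lo - config.presat_ppm) / gamma)) / math.pi
    return S / 9.0 / F


def render_mixture(concs: dict, config: AcquisitionConfig,
                   rng: np.random.Generator = None,
                   axis: np.ndarray = None,
                   water_area: float = None,
                   meta: dict = None) -> Spectrum:
    """Render a metabolite mixture (concentrations in mmol/L) to a spectrum."""
    axis = default_axis(config) if axis is None else axis
    tl = _effective_transitions(
        {k: v / 1000.0 for k, v in concs.items()}, config)  # mol/L scale
    spec = render_spectrum(tl, axis, config.linewidth_Hz, config.field_MHz,
                           meta=meta)
    wa = default_water_residual_area(config) if water_area is None else water_area
    _add_water(spec, config, wa / 1000.0)
    if rng is not None and config.noise_sigma > 0:
        spec.intensity = spec.intensity + rng.normal(
            0.0, config.spectrum_noise_sigma / 1000.0, axis.size)
    spec.meta.setdefault("field_MHz", config.field_MHz)
    spec.meta.setdefault("n_scans", config.n_scans)
    return spec


def generate_calibration_series(analyte: str, concentrations,
                                config: AcquisitionConfig = None,
                                recipe: PreparationRecipe = CALIBRATION_RECIPE,
                                seed: int = 0,
                                axis: np.ndarray = None) -> list:
    """One spectrum per standard concentration (mmol/L), with TSP and water.

    Deterministic under a fixed seed; a zero concentration yields a TSP +
    residual-water-only (blank) spectrum.
    """
    config = config or AcquisitionConfig()
    if analyte not in library.list_metabolites():
        raise KeyError(f"unknown analyte {analyte!r}; library entries: "
                       + ", ".join(library.list_metabolites()))
    if np.any(np.asarray(concentrations, dtype=float) < 0):
        raise ValueError("concentrations must be non-negative")
    tsp_mmolL = tsp_final_concentration(recipe) / 1000.0
    rng = np.random.default_rng(seed)
    axis = default_axis(config) if axis is None else axis
    out = []
    for c in concentrations:
        concs = {"tsp": tsp_mmolL}
        if c > 0:
            concs[analyte] = float(c)
        spec = render_mixture(
            concs, config, rng=rng, axis=axis,
            meta={"analyte": analyte, "concentration": float(c),
                  "tsp_mmolL": tsp_mmolL})
        out.append(spec)
    return out


# ---------------------------------------------------------------------------
# cohort specification and generation

@dataclass(frozen=True)
class MetaboliteDistribution:
    """Group-wise concentration distribution of one metabolite (mmol/L).

    ``mean``/``sd`` are the moments of the positive concentration
    distribution; ``detect_fraction`` zero-inflates (a sample is non-detectable
    with probability 1 − detect_fraction, applied before drawing).
    ``distribution`` ∈ {auto, normal, lognormal}: *normal* draws are
    positive-part truncated (negative draws clip to 0 — physically, levels
    below any detectable amount); *auto* keeps the truncated normal unless
    CV > 1, which a zero-truncated normal cannot represent, in which case a
    moment-matched log-normal is used.  ``anchored`` flags values transcribed
    from the printed group statistics vs. plausible defaults.

    ``loading`` ∈ [−1, 1] couples the metabolite to a per-sample latent
    "disease severity" factor through a Gaussian copula: marginal
    distributions (and the detection fraction) are preserved exactly, but
    within a group the markers co-vary — more severe diabetics have both
    detectable glucose and higher ketone bodies, as real patients do.
    Negative loadings model severity-suppressed metabolites.
    """

    mean: float
    sd: float = 0.0
    detect_fraction: float = 1.0
    distribution: str = "auto"
    anchored: bool = True
    loading: float = 0.0
    #: (mean, sd) of the level in non-detected samples — below the assay's
    #: quantification limit but not zero (e.g. sub-LOQ urinary glucose);
    #: None means absent (level 0)
    undetected: tuple = None

    def __post_init__(self):
        if self.mean < 0 or self.sd < 0:
            raise ValueError("mean and sd must be non-negative")
        if not 0.0 <= self.detect_fraction <= 1.0:
            raise ValueError("detect_fraction must lie in [0, 1]")
        if self.distribution not in ("auto", "normal", "lognormal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if not -1.0 <= self.loading <= 1.0:
            raise ValueError("loading must lie in [-1, 1]")

    @classmethod
    def from_sem(cls, mean, sem, n, **kw) -> "MetaboliteDistribution":
        """Printed mean ± SEM with group size n → SD = SEM·√n."""
        return cls(mean=mean, sd=sem * math.sqrt(n), **kw)

    @property
    def kind(self) -> str:
        if self.distribution != "auto":
            return self.distribution
        if self.sd == 0 or self.mean == 0:
            return "normal"
        return "lognormal" if self.sd > self.mean else "normal"

    def _ppf(self, u: np.ndarray) -> np.ndarray:
        """Marginal quantile function of the (positive) value distribution."""
        from scipy.stats import norm
        if self.sd == 0 or self.mean == 0:
            return np.full(u.shape, self.mean)
        if self.kind == "lognormal":
            s2 = math.log(1.0 + (self.sd / self.mean) ** 2)
            mu = math.log(self.mean) - 0.5 * s2
            return np.exp(mu + math.sqrt(s2) * norm.ppf(u))
        return np.maximum(norm.ppf(u, loc=self.mean, scale=self.sd), 0.0)

    def sample(self, rng: np.random.Generator, n: int,
               latent: np.ndarray = None) -> np.ndarray:
        """Draw n concentrations, optionally coupled to a latent N(0,1).

        With a latent factor z, the copula variate is
        x = loading·z + √(1−loading²)·ε; both the value (via the marginal
        quantile of Φ(x)) and detectability (the top ``detect_fraction`` of
        the copula distribution counts as detectable) derive from x, so
        marginal statistics are preserved while markers co-vary.
        """
        from scipy.stats import norm
        eps = rng.standard_normal(n)
        if latent is None or self.loading == 0.0:
            x = eps
        else:
            x = self.loading * latent + math.sqrt(
                1.0 - self.loading ** 2) * eps
        u = norm.cdf(x)
        detect = u > 1.0 - self.detect_fraction
        # conditional quantile of the detectable upper part of the copula
        u_det = np.clip((u - (1.0 - self.detect_fraction))
                        / max(self.detect_fraction, 1e-12), 1e-9, 1 - 1e-9)
        vals = self._ppf(u_det)
        if self.undetected is None:
            low = np.zeros_like(vals)
        else:
            mu_u, sd_u = self.undetected
            u_nd = np.clip(u / max(1.0 - self.detect_fraction, 1e-12),
                           1e-9, 1 - 1e-9)
            low = np.maximum(norm.ppf(u_nd, loc=mu_u, scale=sd_u), 0.0)
        return np.where(detect, vals, low)


@dataclass(frozen=True)
class CohortSpec:
    """Per-group sample sizes and metabolite distributions.

    ``groups`` maps group name → (size, {metabolite: MetaboliteDistribution});
    ``background`` metabolites are added to every sample at fixed levels.
    """

    groups: tuple  # ((name, size, ((met, dist), ...)), ...)
    background: tuple = ()
    #: CV of the per-sample urinary dilution factor (unit-mean log-normal
    #: multiplying every metabolite of a sample); urine output varies widely
    #: with hydration, which is why creatinine normalisation exists at all
    dilution_cv: float = 0.5

    def __post_init__(self):
        for _name, size, _mets in self.groups:
            if size < 2:
                raise ValueError("group sizes must be >= 2")
        if self.dilution_cv < 0:
            raise ValueError("dilution_cv must be >= 0")

    def group_dict(self) -> dict:
        return {name: (size, dict(mets)) for name, size, mets in self.groups}


def default_cohort_spec() -> CohortSpec:
    """Type 2 diabetic (n=10) vs healthy control (n=14) urine cohort.

    Anchored entries transcribe the printed group statistics (mean ± SEM →
    SD = SEM·√n): 3-hydroxybutyrate 3.12±0.99 vs 0.24±0.06; creatinine
    20.86±10.56 vs 6.30±0.99 mmol/L; total glucose detectable in 6/10
    diabetics with 155±56 mmol/L among detectable samples.  Unanchored
    entries carry plausible urine levels honouring only the reported
    direction of change (ketone bodies, acetate, N-acetyls, lactate and
    methylsuccinate up in diabetes; citrate, hippurate, indoxyl sulphate and
    formate down).
    """
    M = MetaboliteDistribution
    diabetic = (
        ("3_hydroxybutyrate", M.from_sem(3.12, 0.99, 10, loading=0.7)),
        ("glucose", M.from_sem(155.0, 56.0, 6, detect_fraction=0.6,
                               loading=0.9, undetected=(3.0, 2.0))),
        ("creatinine", M.from_sem(20.86, 10.56, 10, loading=0.3)),
        ("acetone", M(0.14, 0.10, anchored=False, loading=0.7)),
        ("acetate", M(0.18, 0.10, anchored=False, loading=0.5)),
        ("n_acetyl", M(0.24, 0.12, anchored=False, loading=0.5)),
        ("lactate", M(0.30, 0.15, anchored=False, loading=0.4)),
        ("methylsuccinate", M(0.10, 0.05, anchored=False, loading=0.4)),
        ("formate", M(0.12, 0.06, anchored=False, loading=-0.3)),
        ("citrate", M(2.00, 1.00, anchored=False, loading=-0.4)),
        ("hippurate", M(2.20, 1.10, anchored=False, loading=-0.4)),
        ("indoxyl_sulfate", M(0.45, 0.20, anchored=False, loading=-0.4)),
    )
    control = (
        ("3_hydroxybutyrate", M.from_sem(0.24, 0.06, 14)),
        ("glucose", M(0.05, 0.03, anchored=False)),
        ("creatinine", M.from_sem(6.30, 0.99, 14)),
        ("acetone", M(0.08, 0.05, anchored=False)),
        ("acetate", M(0.15, 0.08, anchored=False)),
        ("n_acetyl", M(0.20, 0.10, anchored=False)),
        ("lactate", M(0.25, 0.12, anchored=False)),
        ("methylsuccinate", M(0.08, 0.04, anchored=False)),
        ("formate", M(0.15, 0.08, anchored=False)),
        ("citrate", M(2.50, 1.00, anchored=False)),
        ("hippurate", M(2.80, 1.20, anchored=False)),
        ("indoxyl_sulfate", M(0.55, 0.25, anchored=False)),
    )
    background = (("glycine", 0.90), ("tmao", 0.35))
    return CohortSpec(groups=(("diabetic", 10, diabetic),
                              ("control", 14, control)),
                      background=background)


def generate_cohort(spec: CohortSpec = None,
                    config: AcquisitionConfig = None,
                    recipe: PreparationRecipe = BIOFLUID_RECIPE,
                    seed: int = 0,
                    axis: np.ndarray = None):
    """Draw per-sample concentrations and render one spectrum per sample.

    Returns ``(spectra, truth)`` where *truth* is a samples × metabolites
    concentration table (mmol/L) with ``sample`` and ``group`` columns —
    the ground truth for recovery tests.
    """
    spec = spec or default_cohort_spec()
    config = config or AcquisitionConfig()
    rng = np.random.default_rng(seed)
    axis = default_axis(config) if axis is None else axis
    tsp_mmolL = tsp_final_concentration(recipe) / 1000.0
    # supernatant dilution into the final NMR tube volume
    dilution = dict(recipe.aliquots_uL).get("supernatant",
                                            recipe.final_volume_uL)
    dilution /= recipe.final_volume_uL

    rows, spectra = [], []
    for gname, size, mets in spec.groups:
        severity = rng.standard_normal(size)
        draws = {m: d.sample(rng, size, latent=severity) for m, d in mets}
        urine_dilution = _unit_mean_lognormal(rng, spec.dilution_cv, size)
        for i in range(size):
            concs = {m: float(v[i]) for m, v in draws.items()}
            for m, level in spec.background:
                concs[m] = concs.get(m, 0.0) + level
            concs = {m: c * urine_dilution[i] for m, c in concs.items()}
            tube = {m: c * dilution for m, c in concs.items()}
            tube["tsp"] = tsp_mmolL
            sid = f"{gname}_{i + 1:02d}"
            spectra.append(render_mixture(
                tube, config, rng=rng, axis=axis,
                meta={"sample": sid, "group": gname,
                      "tsp_mmolL": tsp_mmolL, "dilution": dilution}))
            rows.append({"sample": sid, "group": gname, **concs})
    truth = pd.DataFrame(rows).fillna(0.0)
    return spectra, truth


# ---------------------------------------------------------------------------
# four-method comparison tables

@dataclass(frozen=True)
class MethodComparisonSpec:
    """Multiplicative model y_ij = µ · bias_i · participant_j · noise_ij.

    Participant factors are log-normal with unit mean and CV
    ``participant_cv``; per-method noise is log-normal with unit mean and the
    method's CV.  Method biases must be positive.
    """

    n_participants: int = 10
    mu: float = 100.0
    participant_cv: float = 1.0
    method_bias: tuple = (("nmr60", 0.929), ("nmr400", 0.820),
                          ("spectrophotometric", 0.988), ("dipstick", 1.287))
    method_cv: tuple = (("nmr60", 0.05), ("nmr400", 0.05),
                        ("spectrophotometric", 0.05), ("dipstick", 0.05))

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValueError("need >= 2 participants")
        if any(b <= 0 for _, b in self.method_bias):
            raise ValueError("method biases must be positive")


def default_method_comparison_spec() -> MethodComparisonSpec:
    """Four-method urinary glucose comparison with printed method means.

    Biases reproduce the reported 92.9 / 82.0 / 98.8 / 128.7 mmol/L method
    means relative to µ = 100 mmol/L; within-method CVs are configuration
    values (the protocol reports no analytical CVs for these methods).
    """
    return MethodComparisonSpec()


def _unit_mean_lognormal(rng, cv, n):
    if cv <= 0:
        return np.ones(n)
    s2 = math.log(1.0 + cv ** 2)
    return rng.lognormal(-0.5 * s2, math.sqrt(s2), n)


def generate_method_comparison(spec: MethodComparisonSpec = None,
                               seed: int = 0) -> pd.DataFrame:
    """Long-format (participant, method, concentration) table."""
    spec = spec or default_method_comparison_spec()
    rng = np.random.default_rng(seed)
    part = spec.mu * _unit_mean_lognormal(rng, spec.participant_cv,
                                          spec.n_participants)
    cvs = dict(spec.method_cv)
    rows = []
    for method, bias in spec.method_bias:
        noise = _unit_mean_lognormal(rng, cvs.get(method, 0.0),
                                     spec.n_participants)
        for j in range(spec.n_participants):
            rows.append({"participant": f"P{j + 1:02d}", "method": method,
                         "concentration": bias * part[j] * noise[j]})
    return pd.DataFrame(rows)
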