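"""Bucket integration, SNR, LOD/LOQ, calibration and normalisation.

Implements the internal-standard quantification protocol: trapezoidal bucket
integrals on the native ppm grid, TSP normalisation, two SNR estimators
(flanking-point mean and 10-largest-noise-points), calibration fitting with
3×/10×-noise LOD/LOQ further constrained by a ≥10% residual-water overlap
rule, and the 100/36 (= 2.78) α-anomer → total glucose conversion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .spin import Spectrum

__all__ = [
    "Bucket",
    "BucketTable",
    "default_bucket_table",
    "EXCLUSION_REGIONS",
    "ALPHA_C1H_BUCKET",
    "GLUCOSE_BULK_BUCKET",
    "ANOMER_CONVERSION_FACTOR",
    "integrate_bucket",
    "bucket_feature_matrix",
    "estimate_snr",
    "tsp_normalize",
    "tsp_normalize_matrix",
    "TSP_BUCKET",
    "constant_sum_normalize",
    "alpha_to_total_glucose",
    "CalibrationModel",
    "fit_calibration",
    "quantify_from_calibration",
    "creatinine_normalize",
    "NOISE_REGION",
]

#: α-glucose C1-H doublet integration window (ppm)
ALPHA_C1H_BUCKET = (5.17, 5.36)
#: bulk glucose ring-proton window (C2-H…C6-H2)
GLUCOSE_BULK_BUCKET = (3.14, 3.99)
#: 100/36: α-anomer (36% abundance) → total glucose
ANOMER_CONVERSION_FACTOR = 100.0 / 36.0
#: signal-free region used for noise estimation (by construction)
NOISE_REGION = (9.0, 9.5)

#: ppm regions with no visible resonances (or residual water) at 60 MHz,
#: removed from all spectra before multivariate analysis
EXCLUSION_REGIONS = (
    (4.41, 5.16), (0.08, 1.02), (1.61, 1.86), (2.42, 2.52), (2.71, 2.97),
    (5.37, 5.56), (5.86, 6.83), (7.09, 7.14), (8.02, 8.14), (8.53, np.inf),
)


@dataclass(frozen=True)
class Bucket:
    low: float
    high: float
    label: str
    anchored: bool = True

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"bucket {self.label!r}: low must be < high")


@dataclass
class BucketTable:
    """Ordered, non-overlapping ppm integration windows plus exclusions."""

    buckets: list
    exclusions: tuple = EXCLUSION_REGIONS

    def __post_init__(self):
        self.buckets = sorted(self.buckets, key=lambda b: b.low)
        for a, b in zip(self.buckets, self.buckets[1:]):
            if b.low < a.high:
                raise ValueError(f"buckets {a.label!r} and {b.label!r} overlap")
        for b in self.buckets:
            for lo, hi in self.exclusions:
                if b.low < hi and lo < b.high:
                    raise ValueError(
                        f"bucket {b.label!r} intersects exclusion ({lo}, {hi})")

    def __len__(self):
        return len(self.buckets)

    @property
    def labels(self):
        return [b.label for b in self.buckets]

    def __getitem__(self, label: str) -> Bucket:
        for b in self.buckets:
            if b.label == label:
                return b
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"low": b.low, "high": b.high, "label": b.label,
              "anchored": b.anchored} for b in self.buckets])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, exclusions=EXCLUSION_REGIONS):
        return cls([Bucket(r.low, r.high, r.label, bool(r.anchored))
                    for r in df.itertuples()], exclusions)


def default_bucket_table() -> BucketTable:
    """The shipped 27-bucket table spanning 1.03–8.52 ppm.

    Twelve named metabolite buckets plus fifteen filler windows (flagged
    unanchored) tiling the remaining unexcluded span.
    """
    text = resources.files("benchnmr.data").joinpath(
        "buckets_default.csv").read_text()
    from io import StringIO
    df = pd.read_csv(StringIO(text), comment="#")
    return BucketTable.from_frame(df)


def integrate_bucket(spectrum: Spectrum, low_ppm: float,
                     high_ppm: float) -> float:
    """Trapezoidal integral over the closed ppm interval [low, high].

    Endpoint ordinates are linearly interpolated so that adjacent buckets sum
    exactly to their union's integral.
    """
    if low_ppm >= high_ppm:
        raise ValueError("low_ppm must be < high_ppm")
    x, y = spectrum.ppm, np.real(spectrum.intensity)
    if low_ppm < x[0] or high_ppm > x[-1]:
        raise ValueError(
            f"bucket [{low_ppm}, {high_ppm}] outside axis "
            f"[{x[0]:.3f}, {x[-1]:.3f}]")
    inner = (x > low_ppm) & (x < high_ppm)
    xs = np.concatenate(([low_ppm], x[inner], [high_ppm]))
    ys = np.concatenate(([np.interp(low_ppm, x, y)], y[inner],
                         [np.interp(high_ppm, x, y)]))
    return float(np.trapezoid(ys, xs))


def bucket_feature_matrix(spectra, table: BucketTable) -> pd.DataFrame:
    """Samples × buckets integral matrix; sample ids/groups from metadata."""
    rows, idx, groups = [], [], []
    for k, s in enumerate(spectra):
        rows.append([integrate_bucket(s, b.low, b.high) for b in table.buckets])
        idx.append(s.meta.get("sample", f"S{k + 1:03d}"))
        groups.append(s.meta.get("group"))
    fm = pd.DataFrame(rows, index=idx, columns=table.labels)
    fm.attrs["state"] = ["raw"]
    if any(g is not None for g in groups):
        fm.attrs["groups"] = groups
    return fm


#: nominal digital resolution of the benchtop acquisition (6.4 s acquisition
#: time → 0.156 Hz/point → 0.0026 ppm/point at 60 MHz); flanking "data
#: points" for SNR estimation are sampled at this spacing
FLANK_STEP_PPM = 0.0026


def estimate_snr(spectrum: Spectrum, peak_ppm: float,
                 method: str = "flank_mean",
                 peak_halfwidth_ppm: float = 0.05,
                 noise_region: tuple = NOISE_REGION,
                 flank_step_ppm: float = FLANK_STEP_PPM) -> float:
    """Peak height over a noise estimate.

    ``flank_mean``: noise is the mean |intensity| of the 10 data points on
    each side flanking the peak window, sampled at the instrument's digital
    resolution (``flank_step_ppm``).  ``top10_noise``: noise is the mean of
    the 10 largest-|intensity| points in the designated signal-free region.
    A noiseless spectrum returns ``inf``.
    """
    x, y = spectrum.ppm, np.real(spectrum.intensity)
    if not x[0] <= peak_ppm <= x[-1]:
        raise ValueError("peak outside axis")
    if noise_region[0] <= peak_ppm <= noise_region[1]:
        raise ValueError("noise region overlaps the peak")
    win = (x >= peak_ppm - peak_halfwidth_ppm) & (x <= peak_ppm + peak_halfwidth_ppm)
    height = float(y[win].max())
    if method == "flank_mean":
        pos = np.concatenate(
            [peak_ppm - peak_halfwidth_ppm - flank_step_ppm * np.arange(1, 11),
             peak_ppm + peak_halfwidth_ppm + flank_step_ppm * np.arange(1, 11)])
        pos = pos[(pos >= x[0]) & (pos <= x[-1])]
        idx = np.unique(np.searchsorted(x, pos))
        noise = float(np.mean(np.abs(y[idx])))
    elif method == "top10_noise":
        mask = (x >= noise_region[0]) & (x <= noise_region[1])
        vals = np.sort(np.abs(y[mask]))[-10:]
        noise = float(np.mean(vals))
    else:
        raise ValueError(f"unknown SNR method {method!r}")
    return math.inf if noise == 0 else height / noise


def tsp_normalize(analyte_area: float, tsp_area: float) -> float:
    """Internal-standard ratio analyte/TSP."""
    if tsp_area <= 0:
        raise ValueError("TSP area must be positive")
    return analyte_area / tsp_area


#: default TSP integration window (ppm) for internal-standard normalisation
TSP_BUCKET = (-0.1, 0.1)


def tsp_normalize_matrix(fm: pd.DataFrame, tsp_areas) -> pd.DataFrame:
    """Divide each sample's bucket row by its TSP internal-standard area."""
    tsp = np.asarray(tsp_areas, dtype=float)
    if tsp.shape != (len(fm),):
        raise ValueError("one TSP area per sample required")
    if np.any(tsp <= 0):
        raise ValueError("TSP areas must be positive")
    out = fm.div(tsp, axis=0)
    out.attrs = dict(fm.attrs)
    out.attrs["state"] = list(fm.attrs.get("state", ["raw"])) + ["tsp"]
    return out


def constant_sum_normalize(fm: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample's bucket row to sum to 1 (100%)."""
    vals = fm.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("constant-sum normalisation requires non-negative buckets")
    sums = vals.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        raise ValueError(
            "zero-sum sample(s): " + ", ".join(map(str, fm.index[zero])))
    out = fm.div(sums, axis=0)
    out.attrs = dict(fm.attrs)
    out.attrs["state"] = list(fm.attrs.get("state", ["raw"])) + ["csn"]
    return out


def alpha_to_total_glucose(alpha_conc) -> float:
    """Convert an α-anomer concentration to total glucose: × 100/36 = 2.78."""
    if np.any(np.asarray(alpha_conc) < 0):
        raise ValueError("concentration must be non-negative")
    out = np.asarray(alpha_conc, dtype=float) * ANOMER_CONVERSION_FACTOR
    return float(out) if np.isscalar(alpha_conc) else out


@dataclass
class CalibrationModel:
    """Least-squares calibration of a TSP-normalised resonance."""

    slope: float
    intercept: float
    r: float
    lod: float
    loq_snr: float
    loq_water_limited: float
    analyte: str = ""
    resonance_ppm: float = float("nan")

    @property
    def loq(self) -> float:
        vals = [v for v in (self.loq_snr, self.loq_water_limited)
                if np.isfinite(v)]
        return max(vals) if vals else float("nan")

    def __post_init__(self):
        if not -1.0 <= round(self.r, 12) <= 1.0:
            raise ValueError("correlation outside [-1, 1]")


def fit_calibration(concentrations, tsp_ratios, snr_per_point=None,
                    water_overlap_fractions=None, analyte: str = "",
                    resonance_ppm: float = float("nan"),
                    snr_lod: float = 3.0, snr_loq: float = 10.0,
                    max_water_overlap: float = 0.10) -> CalibrationModel:
    """Fit a calibration line and derive LOD/LOQ.

    LOD/LOQ are the lowest calibration concentrations whose SNR reaches 3×
    and 10× the noise; the LOQ is additionally raised to the lowest
    concentration whose residual-water overlap fraction falls below 10% —
    the protocol's overlap criterion that sets the 8.0 mmol/L glucose LOQ.
    """
    c = np.asarray(concentrations, dtype=float)
    rr = np.asarray(tsp_ratios, dtype=float)
    if c.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.unique(c).size < 2:
        raise ValueError("concentrations must be distinct")
    res = stats.linregress(c, rr)
    lod = loq_snr = float("nan")
    if snr_per_point is not None:
        snr = np.asarray(snr_per_point, dtype=float)
        ok = snr >= snr_lod
        if ok.any():
            lod = float(c[ok].min())
        ok = snr >= snr_loq
        if ok.any():
            loq_snr = float(c[ok].min())
    loq_water = float("nan")
    if water_overlap_fractions is not None:
        w = np.asarray(water_overlap_fractions, dtype=float)
        ok = w < max_water_overlap
        if ok.any():
            loq_water = float(c[ok].min())
    model = CalibrationModel(
        slope=float(res.slope), intercept=float(res.intercept),
        r=float(res.rvalue), lod=lod, loq_snr=loq_snr,
        loq_water_limited=loq_water, analyte=analyte,
        resonance_ppm=resonance_ppm)
    return model


def quantify_from_calibration(tsp_ratio: float, model: CalibrationModel):
    """Invert the calibration line: (ratio − intercept)/slope.

    Returns ``(concentration, below_loq)``; negative estimates clamp to 0
    with the flag set.
    """
    if model.slope <= 0:
        raise ValueError("calibration slope must be positive")
    conc = (tsp_ratio - model.intercept) / model.slope
    flag = bool(np.isfinite(model.loq) and conc < model.loq)
    if conc < 0:
        return 0.0, True
    return float(conc), flag


def creatinine_normalize(fm: pd.DataFrame, cn_label: str = "creatinine",
                         table: BucketTable = None,
                         glucose_region: tuple = GLUCOSE_BULK_BUCKET):
    """Divide every bucket by the creatinine bucket, with a feasibility flag.

    At 60 MHz the bulk glucose ring-proton envelope overlaps creatinine's
    resonances in high-glucose (diabetic) samples, making Cn normalisation
    unreliable; when the Cn bucket's bounds intersect the glucose bulk region
    a warning is raised and the returned flag is False.
    """
    if cn_label not in fm.columns:
        raise KeyError(f"no bucket {cn_label!r} in the feature matrix")
    cn = fm[cn_label].to_numpy(dtype=float)
    if np.any(cn == 0):
        raise ValueError("zero creatinine bucket value")
    feasible = True
    if table is not None:
        b = table[cn_label]
        if b.low <= glucose_region[1] and glucose_region[0] <= b.high:
            feasible = False
            warnings.warn(
                "creatinine bucket overlaps the bulk glucose region; "
                "Cn normalisation is unreliable for high-glucose samples "
                "at 60 MHz", UserWarning)
    out = fm.div(cn, axis=0)
    out.attrs = dict(fm.attrs)
    out.attrs["state"] = list(fm.attrs.get("state", ["raw"])) + ["cn"]
    return out, feasible
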