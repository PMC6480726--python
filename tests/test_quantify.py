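"""Quantification protocol: bucket integrals, SNR, normalisation,
calibration with LOD/LOQ, anomer conversion."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from benchnmr import cohort as coh
from benchnmr import quantify as q
from benchnmr.preprocess import baseline_correct
from benchnmr.spin import AcquisitionConfig, Spectrum, TransitionList, \
    render_spectrum


def lorentzian_spectrum(centre=5.0, area=1.0, fwhm_ppm=0.01,
                        lo=0.0, hi=10.0, step=5e-4):
    x = np.arange(lo, hi, step)
    g = fwhm_ppm / 2
    return Spectrum(x, area * g / np.pi / ((x - centre) ** 2 + g ** 2))


class TestIntegrateBucket:
    def test_zero_spectrum(self):
        spec = Spectrum(np.linspace(0, 10, 1000), np.zeros(1000))
        assert q.integrate_bucket(spec, 2.0, 3.0) == 0.0

    def test_unit_area_lorentzian(self):
        spec = lorentzian_spectrum()
        assert q.integrate_bucket(spec, 4.0, 6.0) == pytest.approx(1.0,
                                                                   rel=0.01)

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(1.0, 4.0), st.floats(4.5, 6.0), st.floats(6.5, 9.0))
    def test_adjacent_buckets_sum_to_union(self, a, b, c):
        spec = lorentzian_spectrum(centre=5.2)
        left = q.integrate_bucket(spec, a, b)
        right = q.integrate_bucket(spec, b, c)
        union = q.integrate_bucket(spec, a, c)
        assert left + right == pytest.approx(union, rel=1e-12, abs=1e-15)

    def test_outside_axis_rejected(self):
        spec = lorentzian_spectrum()
        with pytest.raises(ValueError, match="outside"):
            q.integrate_bucket(spec, 9.0, 11.0)


class TestEstimateSnr:
    def test_noiseless_peak_infinite(self):
        # a compactly supported peak with a silent noise region: both
        # estimators → inf
        x = np.arange(0, 10, 5e-4)
        y = np.maximum(1.0 - np.abs(x - 5.0) / 0.01, 0.0)
        spec = Spectrum(x, y)
        assert q.estimate_snr(spec, 5.0) == math.inf
        assert q.estimate_snr(spec, 5.0, "top10_noise") == math.inf

    def test_flank_mean_value(self):
        x = np.arange(0, 10, 5e-4)
        y = np.ones_like(x)  # flat "noise floor" of 1
        y[np.abs(x - 5.0) < 0.001] = 30.0
        spec = Spectrum(x, y)
        assert q.estimate_snr(spec, 5.0) == pytest.approx(30.0)

    def test_top10_not_larger_than_flank(self, config60):
        # the ten largest noise points bound the flank mean from above
        s, = coh.generate_calibration_series("glucose", [8.0], config60,
                                             seed=3)
        sb = baseline_correct(s)
        a = q.estimate_snr(sb, 5.25, "flank_mean")
        b = q.estimate_snr(sb, 5.25, "top10_noise")
        assert b <= a

    def test_noise_region_overlap_rejected(self):
        spec = lorentzian_spectrum(centre=9.2)
        with pytest.raises(ValueError, match="overlap"):
            q.estimate_snr(spec, 9.2)


class TestNormalisation:
    def test_tsp_ratio_trivial(self):
        assert q.tsp_normalize(3.0, 3.0) == 1.0
        assert q.tsp_normalize(0.0, 2.0) == 0.0
        with pytest.raises(ValueError):
            q.tsp_normalize(1.0, 0.0)

    def test_theoretical_glucose_tsp_ratio(self):
        # 100 mmol/L glucose vs 223 µmol/L TSP: (0.36×100×1H)/(0.223×9H)
        ratio = (0.36 * 100.0 * 1) / (0.223 * 9)
        assert ratio == pytest.approx(17.94, abs=0.01)

    def test_constant_sum_rows(self):
        fm = pd.DataFrame([[1.0, 3.0], [2.0, 2.0]])
        out = q.constant_sum_normalize(fm)
        np.testing.assert_allclose(out.sum(axis=1), 1.0)
        np.testing.assert_allclose(out.iloc[0], [0.25, 0.75])
        assert "csn" in out.attrs["state"]

    def test_constant_sum_scale_invariance(self):
        fm = pd.DataFrame([[1.0, 3.0]])
        doubled = q.constant_sum_normalize(fm * 2)
        pd.testing.assert_frame_equal(q.constant_sum_normalize(fm), doubled)

    def test_constant_sum_zero_row_named(self):
        fm = pd.DataFrame([[0.0, 0.0]], index=["S1"])
        with pytest.raises(ValueError, match="S1"):
            q.constant_sum_normalize(fm)


class TestAnomerConversion:
    @pytest.mark.parametrize("alpha,total", [(36.0, 100.0), (1.0, 2.78),
                                             (0.0, 0.0)])
    def test_factor(self, alpha, total):
        assert q.alpha_to_total_glucose(alpha) == pytest.approx(total,
                                                                abs=0.005)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            q.alpha_to_total_glucose(-1.0)


class TestCalibration:
    def test_exact_linear_data(self):
        c = np.array([1.0, 2.0, 3.0, 4.0])
        model = q.fit_calibration(c, 0.5 * c)
        assert model.r == pytest.approx(1.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)

    def test_lod_loq_from_snr_and_overlap(self):
        c = np.array([1.0, 2.0, 5.0, 7.5, 8.0, 10.0])
        snr = np.array([2.0, 4.0, 12.0, 18.0, 20.0, 25.0])
        overlap = np.array([0.5, 0.4, 0.15, 0.103, 0.097, 0.08])
        model = q.fit_calibration(c, 0.1 * c, snr, overlap)
        assert model.lod == 2.0       # first point with SNR >= 3
        assert model.loq_snr == 5.0   # first point with SNR >= 10
        assert model.loq_water_limited == 8.0
        assert model.loq == 8.0       # overlap criterion dominates
        assert model.loq >= model.lod

    def test_lod_loq_monotone_in_noise(self, bucket_table):
        concs = [2.0, 5.0, 8.0, 20.0, 50.0]
        loqs, lods = [], []
        for ns in (8.0, 32.0, 128.0):
            cfg = AcquisitionConfig(noise_sigma=ns)
            series = coh.generate_calibration_series("glucose", concs, cfg,
                                                     seed=5)
            snr, ratios = [], []
            for s in series:
                sb = baseline_correct(s)
                snr.append(q.estimate_snr(sb, 5.25))
                ratios.append(q.integrate_bucket(sb, *q.ALPHA_C1H_BUCKET)
                              / q.integrate_bucket(sb, *q.TSP_BUCKET))
            m = q.fit_calibration(concs, ratios, snr)
            lods.append(m.lod)
            loqs.append(m.loq_snr)
        assert lods == sorted(lods)
        assert loqs == sorted(loqs)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            q.fit_calibration([1.0, 2.0], [0.1, 0.2])

    def test_inversion_and_flags(self):
        model = q.CalibrationModel(slope=0.5, intercept=0.1, r=1.0,
                                   lod=1.0, loq_snr=3.0,
                                   loq_water_limited=8.0)
        assert q.quantify_from_calibration(0.1, model) == (0.0, True)
        conc, flag = q.quantify_from_calibration(0.5 * 50 + 0.1, model)
        assert conc == pytest.approx(50.0)
        assert not flag
        conc, flag = q.quantify_from_calibration(0.05, model)
        assert conc == 0.0 and flag

    def test_nonpositive_slope_rejected(self):
        model = q.CalibrationModel(slope=-0.5, intercept=0.0, r=-1.0,
                                   lod=1.0, loq_snr=1.0,
                                   loq_water_limited=1.0)
        with pytest.raises(ValueError):
            q.quantify_from_calibration(1.0, model)

    def test_end_to_end_recovery_within_5pct(self, noise_free60):
        """A 155 mmol/L sample quantified through the fitted calibration."""
        concs = [50, 100, 200, 300, 400, 500, 600]
        series = coh.generate_calibration_series("glucose", concs,
                                                 noise_free60, seed=2)
        ratios = []
        for s in series:
            sb = baseline_correct(s)
            ratios.append(q.integrate_bucket(sb, *q.ALPHA_C1H_BUCKET)
                          / q.integrate_bucket(sb, *q.TSP_BUCKET))
        model = q.fit_calibration(concs, ratios)
        sample, = coh.generate_calibration_series("glucose", [155.0],
                                                  noise_free60, seed=2)
        sb = baseline_correct(sample)
        ratio = q.integrate_bucket(sb, *q.ALPHA_C1H_BUCKET) \
            / q.integrate_bucket(sb, *q.TSP_BUCKET)
        conc, _ = q.quantify_from_calibration(ratio, model)
        assert conc == pytest.approx(155.0, rel=0.05)

    def test_quantification_linearity(self, noise_free60):
        a, b = coh.generate_calibration_series("glucose", [100.0, 200.0],
                                               noise_free60, seed=2)
        ra = q.integrate_bucket(baseline_correct(a), *q.ALPHA_C1H_BUCKET)
        rb = q.integrate_bucket(baseline_correct(b), *q.ALPHA_C1H_BUCKET)
        assert rb / ra == pytest.approx(2.0, rel=0.01)


class TestBucketTable:
    def test_default_table_shape(self, bucket_table):
        assert len(bucket_table) == 27
        assert bucket_table.buckets[0].low >= 1.03
        assert bucket_table.buckets[-1].high <= 8.52
        named = [b for b in bucket_table.buckets if b.anchored]
        assert len(named) >= 12
        assert "glucose_c1h" in bucket_table.labels
        b = bucket_table["glucose_c1h"]
        assert (b.low, b.high) == q.ALPHA_C1H_BUCKET

    def test_overlapping_buckets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            q.BucketTable([q.Bucket(1.0, 2.0, "a"), q.Bucket(1.5, 2.5, "b")],
                          exclusions=())

    def test_bucket_in_exclusion_rejected(self):
        with pytest.raises(ValueError, match="exclusion"):
            q.BucketTable([q.Bucket(4.5, 4.6, "water-ish")])

    def test_round_trip_frame(self, bucket_table):
        df = bucket_table.to_frame()
        again = q.BucketTable.from_frame(df)
        assert again.labels == bucket_table.labels


class TestCreatinineNormalize:
    def test_unit_cn_identity(self):
        fm = pd.DataFrame({"creatinine": [1.0, 1.0], "x": [2.0, 3.0]})
        out, feasible = q.creatinine_normalize(fm)
        np.testing.assert_allclose(out["x"], [2.0, 3.0])
        assert feasible

    def test_60mhz_glucose_interference_warning(self, bucket_table):
        fm = pd.DataFrame({"creatinine": [1.0], "glucose_bulk": [155.0]})
        with pytest.warns(UserWarning, match="glucose"):
            _out, feasible = q.creatinine_normalize(fm, table=bucket_table)
        assert not feasible

    def test_narrow_cn_bucket_feasible(self):
        # a 400 MHz-style narrow Cn bucket clear of the glucose envelope
        table = q.BucketTable([q.Bucket(3.01, 3.05, "creatinine"),
                               q.Bucket(1.17, 1.23, "3hb")], exclusions=())
        fm = pd.DataFrame({"creatinine": [2.0], "3hb": [4.0]})
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            out, feasible = q.creatinine_normalize(fm, table=table)
        assert feasible
        assert out["3hb"].iloc[0] == pytest.approx(2.0)

    def test_cn_ratio_recovery_at_400mhz(self):
        """On a noise-free 400 MHz render, the 3-HB/Cn bucket ratio tracks
        the true concentration ratio within 10%."""
        cfg = AcquisitionConfig(field_MHz=400.0, presat_ppm=4.80,
                                presat_power_dB=50.0, noise_sigma=0.0)
        truth = {"3_hydroxybutyrate": 3.1, "creatinine": 20.9}
        spec = coh.render_mixture(truth, cfg, water_area=0.0)
        hb = q.integrate_bucket(spec, 1.17, 1.23)      # CH3 doublet, 3H
        cn = q.integrate_bucket(spec, 3.00, 3.06)      # N-CH3 singlet, 3H
        measured = hb / cn
        expected = truth["3_hydroxybutyrate"] / truth["creatinine"]
        assert measured == pytest.approx(expected, rel=0.10)

    def test_zero_cn_rejected(self):
        fm = pd.DataFrame({"creatinine": [0.0], "x": [1.0]})
        with pytest.raises(ValueError):
            q.creatinine_normalize(fm)
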