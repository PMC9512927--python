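import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from compcal import (
    CalibrationDesign,
    CompressedCalibration,
    ElementCalibration,
    IntensityMatrix,
    MissingCalibrationError,
    NonPositiveSensitivityError,
    estimates_to_frame,
    invert_intensity,
    quantify_mean_intensity,
    quantify_sample,
    simulate_design,
    simulate_survey,
)
from conftest import mc_inversion_sd


class TestInvertIntensity:
    def test_noiseless_inversion(self):
        calib = ElementCalibration(background=10.0, sensitivity=100.0, residual_sd=0.0,
                                   var_background=0.0, var_sensitivity=0.0,
                                   cov_bg_sens=0.0, n_points=3)
        r, sd = invert_intensity(calib, 60.0)
        assert (r, sd) == (0.5, 0.0)

    def test_delta_method_value(self, oracle_calibration):
        # (sigma^2 + var_b + r^2 var_s + 2 r cov) / s^2 = 14.25e-4
        r, sd = invert_intensity(oracle_calibration, 60.0, m=1)
        assert r == pytest.approx(0.5)
        assert sd == pytest.approx(np.sqrt(14.25) / 100, rel=1e-12)
        assert sd == pytest.approx(0.037749, abs=5e-7)

    def test_replicates_shrink_sample_noise_term(self, oracle_calibration):
        r, sd = invert_intensity(oracle_calibration, 60.0, m=2)
        assert r == pytest.approx(0.5)
        assert sd == pytest.approx(0.031225, abs=5e-7)

    @pytest.mark.parametrize("m", [1, 2])
    def test_monte_carlo_oracle_agreement(self, oracle_calibration, m):
        """Delta-method sd within 2% of a 10^6-draw Monte-Carlo propagation."""
        _, sd = invert_intensity(oracle_calibration, 60.0, m=m)
        mc = mc_inversion_sd(oracle_calibration, 60.0, m=m)
        assert sd == pytest.approx(mc, rel=0.02)

    def test_non_positive_sensitivity_refused(self):
        calib = ElementCalibration(background=10.0, sensitivity=-5.0, residual_sd=1.0,
                                   var_background=1.0, var_sensitivity=1.0,
                                   cov_bg_sens=0.0, n_points=3)
        with pytest.raises(NonPositiveSensitivityError):
            invert_intensity(calib, 60.0)

    def test_negative_bracket_clips_to_zero_with_warning(self):
        # A valid covariance matrix keeps the propagated variance >= sigma^2/m,
        # so this branch only guards against externally supplied calibrations
        # whose covariance slightly violates the Cauchy-Schwarz bound.
        calib = ElementCalibration(background=0.0, sensitivity=100.0, residual_sd=0.0,
                                   var_background=1.0, var_sensitivity=1.0,
                                   cov_bg_sens=-1.0, n_points=3)
        object.__setattr__(calib, "cov_bg_sens", -1.01)
        with pytest.warns(UserWarning, match="clipping"):
            _, sd = invert_intensity(calib, 100.0)
        assert sd == 0.0


class TestQuantifySample:
    def _assay(self, values, channels=("63Cu",), ids=None):
        values = np.atleast_2d(np.asarray(values, dtype=float))
        ids = ids or [f"a{i}" for i in range(values.shape[0])]
        return IntensityMatrix(ids, ["assay"] * len(ids), list(channels), values)

    def test_concentration_scaling(self, oracle_calibration):
        (est,) = quantify_sample([oracle_calibration], self._assay([[60.0]]))
        assert est.concentration == pytest.approx(100.0)
        assert est.sd == pytest.approx(7.5498, abs=5e-5)
        assert est.concentration == est.dilution_estimate * oracle_calibration.c0

    def test_below_background_flag(self, oracle_calibration):
        (est,) = quantify_sample([oracle_calibration], self._assay([[5.0]]))
        assert est.concentration < 0
        assert est.flag == "below_background"

    def test_extrapolation_flag(self, oracle_calibration):
        (est,) = quantify_sample([oracle_calibration], self._assay([[150.0]]))
        assert est.dilution_estimate > 1
        assert est.flag == "extrapolated_above_standard"

    def test_doubling_c0_doubles_conc_and_sd(self, oracle_calibration):
        from dataclasses import replace
        (e1,) = quantify_sample([oracle_calibration], self._assay([[60.0]]))
        (e2,) = quantify_sample([replace(oracle_calibration, c0=400.0)], self._assay([[60.0]]))
        assert e2.concentration == 2 * e1.concentration
        assert e2.sd == 2 * e1.sd

    def test_missing_calibration_keyed_error(self, oracle_calibration):
        with pytest.raises(MissingCalibrationError, match="27Al"):
            quantify_sample([oracle_calibration], self._assay([[1.0, 2.0]], ("63Cu", "27Al")))

    def test_non_positive_sensitivity_flagged_nan(self, oracle_calibration):
        from dataclasses import replace
        bad = replace(oracle_calibration, sensitivity=-1.0, channel="27Al", element="Al")
        ests = quantify_sample([oracle_calibration, bad],
                               self._assay([[60.0, 50.0]], ("63Cu", "27Al")))
        flags = {e.channel: e.flag for e in ests}
        assert flags["27Al"] == "non_positive_sensitivity"
        assert np.isnan([e for e in ests if e.channel == "27Al"][0].concentration)


class TestQuantifyMeanIntensity:
    def test_single_sample_reduces_to_quantify_sample(self, oracle_calibration):
        assay = IntensityMatrix(["a0"], ["assay"], ["63Cu"], [[60.0]])
        (pooled,) = quantify_mean_intensity([oracle_calibration], assay, label="a0")
        (single,) = quantify_sample([oracle_calibration], assay)
        assert pooled.concentration == single.concentration
        assert pooled.sd == single.sd

    def test_two_sample_pooling_oracle_case(self, oracle_calibration):
        assay = IntensityMatrix(["a0", "a1"], ["assay"] * 2, ["63Cu"], [[55.0], [65.0]])
        (est,) = quantify_mean_intensity([oracle_calibration], assay)
        assert est.concentration == pytest.approx(100.0)
        assert est.m == 2
        assert est.sd == pytest.approx(6.2450, abs=5e-5)
        mc = mc_inversion_sd(oracle_calibration, 60.0, m=2)
        assert est.sd == pytest.approx(mc * oracle_calibration.c0, rel=0.02)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_mean_of_estimates_equals_estimate_of_mean(self, seed, oracle_calibration):
        """Linearity: pooling intensities first changes only the sd."""
        rng = np.random.default_rng(seed)
        vals = rng.uniform(20, 200, (6, 1))
        assay = IntensityMatrix([f"a{i}" for i in range(6)], ["assay"] * 6, ["63Cu"], vals)
        singles = quantify_sample([oracle_calibration], assay)
        (pooled,) = quantify_mean_intensity([oracle_calibration], assay)
        mean_c = np.mean([e.concentration for e in singles])
        assert pooled.concentration == pytest.approx(mean_c, rel=1e-12)
        # pooling only shrinks the sample-noise term relative to a single
        # measurement at the same mean intensity
        _, sd_single = invert_intensity(oracle_calibration, float(vals.mean()), m=1)
        assert pooled.sd < sd_single * oracle_calibration.c0

    def test_empty_subset_rejected(self, oracle_calibration):
        assay = IntensityMatrix(["a0"], ["assay"], ["63Cu"], [[60.0]])
        with pytest.raises(ValueError):
            quantify_mean_intensity([oracle_calibration], assay, sample_ids=[])


class TestEndToEnd:
    def test_noiseless_round_trip_recovers_truth(self, noiseless_run):
        """simulate(sigma*=0) -> fit -> quantify returns every truth to 1e-9."""
        design, truth, matrix = noiseless_run
        res = CompressedCalibration(matrix, design).fit()
        df = estimates_to_frame(
            quantify_sample(res.calibrations, CompressedCalibration(matrix, design).assay_part,
                            design=design)
        )
        truth_c = truth.concentration_truth
        for row in df.itertuples():
            expected = truth_c.at[row.sample_id, row.element]
            if expected == 0.0:
                assert abs(row.concentration) < 1e-6
            else:
                assert row.concentration == pytest.approx(expected, rel=1e-9)

    def test_undiluted_mixture_returns_r_of_one(self, noiseless_run):
        """Quantifying the d=1 standard itself gives r = 1, c = C0."""
        design, truth, matrix = noiseless_run
        res = CompressedCalibration(matrix, design).fit()
        cal_part = CompressedCalibration(matrix, design).calibration_part
        top = [s for s, d in design.dilution_factors.items() if d == 1.0]
        sub = cal_part.select_samples(top)
        sub = IntensityMatrix(sub.sample_ids, ["assay"], sub.channels, sub.intensities)
        for est in quantify_sample(res.calibrations, sub):
            assert est.dilution_estimate == pytest.approx(1.0, abs=1e-12)
            assert est.concentration == pytest.approx(
                design.mixture_composition[est.element], rel=1e-12)

    def test_coverage_with_t_quantile(self):
        """(ĉ − c)/sd is a 3-df t pivot at the 5-level design: t-based 95%
        intervals cover in [93%, 97%] while 1.96·sd intervals undercover."""
        from scipy import stats

        from compcal import fit_element_calibration

        rng = np.random.default_rng(77)
        d = np.array([1.0, 0.5, 0.1, 0.01, 0.0])
        b_t, s_t, sigma, r_t = 50.0, 1000.0, 5.0, 0.4
        q_t = stats.t.ppf(0.975, 3)
        hits_t = hits_n = 0
        n_rep = 2000
        for _ in range(n_rep):
            I = b_t + s_t * d + rng.normal(0, sigma, 5)
            fit = fit_element_calibration(d, I)
            I_a = b_t + s_t * r_t + rng.normal(0, sigma)
            r, sd = invert_intensity(fit, I_a)
            hits_t += abs(r - r_t) <= q_t * sd
            hits_n += abs(r - r_t) <= 1.96 * sd
        assert 0.93 <= hits_t / n_rep <= 0.97
        assert hits_n / n_rep < 0.93  # the normal quantile undercovers at 3 df
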