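import numpy as np
import pytest

from cholbind.pharm import (
    DoseResponseDataset,
    DoseResponseFit,
    agonism_index,
    cholesterol_response_regression,
    fit_bell,
    fit_logistic3,
    gi_component,
    glucagon_alanine_index,
)
from cholbind.synthetic import BellTruth, generate_dose_response

CONC = np.logspace(-12.5, -6.5, 10)


def logistic(c, basal, emax, ec50):
    return basal + (emax - basal) / (1 + ec50 / c)


class TestLogistic3:
    def test_noiseless_recovery(self):
        ds = DoseResponseDataset(CONC, logistic(CONC, 0.0, 100.0, 1e-10))
        fit = fit_logistic3(ds)
        assert fit.basal == pytest.approx(0.0, abs=1e-6)
        assert fit.emax == pytest.approx(100.0, abs=1e-6)
        assert fit.ec50_m == pytest.approx(1e-10, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_midpoint_identity(self):
        ds = DoseResponseDataset(CONC, logistic(CONC, 10.0, 90.0, 3e-10))
        fit = fit_logistic3(ds)
        mid = fit.predict(np.array([fit.ec50_m]))[0]
        assert mid == pytest.approx((fit.basal + fit.emax) / 2, rel=1e-6)

    def test_too_few_concentrations_rejected(self):
        c = np.array([1e-11, 1e-10, 1e-9])
        with pytest.raises(ValueError):
            fit_logistic3(DoseResponseDataset(c, logistic(c, 0, 1, 1e-10)))

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            DoseResponseDataset(np.array([0.0, 1e-9]), np.array([0.0, 1.0]))


class TestBell:
    def test_noiseless_tenfold_separation_recovered_within_1pct(self):
        truth = BellTruth()  # EC50_i / EC50_s = 10
        ds = DoseResponseDataset(CONC, truth.total(CONC))
        fit = fit_bell(ds)
        assert fit.span_s == pytest.approx(truth.span_s, rel=0.01)
        assert fit.span_i == pytest.approx(truth.span_i, rel=0.01)
        assert fit.ec50_s_m == pytest.approx(truth.ec50_s_m, rel=0.01)
        assert fit.ec50_i_m == pytest.approx(truth.ec50_i_m, rel=0.01)
        assert fit.ec50_i_m / fit.ec50_s_m == pytest.approx(10.0, rel=0.01)

    def test_no_inhibitory_span_collapses_to_logistic3(self):
        ds = DoseResponseDataset(CONC, logistic(CONC, 5.0, 105.0, 2e-10))
        bell = fit_bell(ds)
        assert bell.collapsed_to_logistic3
        log3 = fit_logistic3(ds)
        assert bell.basal == pytest.approx(log3.basal, abs=0.05)
        assert bell.basal + bell.span_s == pytest.approx(log3.emax, rel=1e-3)
        assert bell.ec50_s_m == pytest.approx(log3.ec50_m, rel=1e-3)

    def test_curve_maximum_lies_between_the_two_ec50s(self):
        truth = BellTruth()
        ds = DoseResponseDataset(CONC, truth.total(CONC))
        fit = fit_bell(ds)
        grid = np.logspace(-13, -6, 4000)
        c_max = grid[int(np.argmax(fit.predict(grid)))]
        assert fit.ec50_s_m < c_max < fit.ec50_i_m

    def test_inhibitory_ec50_never_below_stimulatory(self):
        rng = np.random.default_rng(6)
        truth = BellTruth()
        ds = DoseResponseDataset(
            CONC, truth.total(CONC) + rng.normal(0, 2.0, CONC.size))
        fit = fit_bell(ds)
        assert fit.ec50_i_m >= fit.ec50_s_m


class TestGiComponent:
    def test_identical_curves_give_zero_component(self):
        ds = DoseResponseDataset(CONC, logistic(CONC, 0, 100, 1e-10))
        comp = gi_component(ds, ds)
        np.testing.assert_allclose(comp["gi_component"], 0.0)
        assert comp.attrs["auc"] == pytest.approx(0.0)

    def test_recovers_generated_inhibitory_component(self):
        total, ptx, truth = generate_dose_response(noise_sd=2.0,
                                                   n_replicates=6, seed=8)
        comp = gi_component(total, ptx)
        expected = truth.inhibitory(comp["concentration_M"].to_numpy())
        resid = comp["gi_component"].to_numpy() - expected
        assert np.abs(resid).max() < 3 * 2.0  # within noise SD scale
        true_auc = float(np.trapezoid(
            truth.inhibitory(CONC), np.log10(CONC)))
        assert comp.attrs["auc"] == pytest.approx(true_auc, rel=0.05)

    def test_mismatched_grids_rejected(self):
        ds1 = DoseResponseDataset(CONC, logistic(CONC, 0, 100, 1e-10))
        other = CONC.copy()
        other[3] *= 1.5
        ds2 = DoseResponseDataset(other, logistic(other, 0, 100, 1e-10))
        with pytest.raises(ValueError):
            gi_component(ds1, ds2)


def _fit(emax, ec50, basal=0.0):
    return DoseResponseFit(model="logistic3", basal=basal, emax=emax,
                           ec50_m=ec50, r_squared=1.0)


class TestAgonismIndex:
    def test_vehicle_against_itself_is_zero(self):
        v = _fit(100.0, 1e-10)
        assert agonism_index(v, v).value == 0.0

    def test_double_emax_half_ec50_gives_log10_four(self):
        v = _fit(100.0, 1e-10)
        t = _fit(200.0, 5e-11)
        assert agonism_index(t, v).value == pytest.approx(np.log10(4.0))

    def test_nonpositive_parameters_rejected(self):
        v = _fit(100.0, 1e-10)
        bad = _fit(-5.0, 1e-10)
        with pytest.raises(ValueError):
            agonism_index(bad, v)

    def test_invariant_to_common_response_rescaling(self):
        rng = np.random.default_rng(13)
        resp_v = logistic(CONC, 2.0, 90.0, 2e-10) + rng.normal(0, 1, CONC.size)
        resp_t = logistic(CONC, 2.0, 120.0, 1e-10) + rng.normal(0, 1, CONC.size)
        idx1 = agonism_index(
            fit_logistic3(DoseResponseDataset(CONC, resp_t)),
            fit_logistic3(DoseResponseDataset(CONC, resp_v)))
        idx2 = agonism_index(
            fit_logistic3(DoseResponseDataset(CONC, 7.5 * resp_t)),
            fit_logistic3(DoseResponseDataset(CONC, 7.5 * resp_v)))
        assert idx2.value == pytest.approx(idx1.value, abs=1e-6)


class TestRegression:
    def test_collinear_points(self):
        x = np.array([0.5, 1.0, 1.5, 2.0])
        res = cholesterol_response_regression(x, -1.0 * x + 0.3)
        assert res["slope"] == pytest.approx(-1.0)
        assert res["intercept"] == pytest.approx(0.3)
        assert res["r_squared"] == pytest.approx(1.0)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            cholesterol_response_regression(np.array([1.0, 2.0]),
                                            np.array([1.0, 2.0]))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cholesterol_response_regression(np.ones(4), np.arange(4.0))

    def test_ci_covers_true_slope_in_at_least_90_of_100_repeats(self):
        rng = np.random.default_rng(99)
        covered = 0
        for _ in range(100):
            x = np.linspace(0.5, 2.0, 8)
            y = -0.8 * x + 0.2 + rng.normal(0, 0.15, x.size)
            lo, hi = cholesterol_response_regression(x, y)["slope_ci95"]
            covered += lo <= -0.8 <= hi
        assert covered >= 90


class TestGlucagonAlanineIndex:
    @pytest.mark.parametrize("glucagon, alanine, expected", [
        (9.2, 1.0, 9.2),   # control-range fasting glucagon, unit alanine
        (0.0, 5.0, 0.0),
        (12.0, 2.0, 24.0),
    ])
    def test_product(self, glucagon, alanine, expected):
        assert glucagon_alanine_index(glucagon, alanine) == \
            pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            glucagon_alanine_index(-1.0, 1.0)
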