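import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

import bioenergize as bz
from bioenergize.calibration import akaike_weights
from bioenergize.synthetic import RespirometryScenario, generate_respirometry


def _noiseless_records(log_s=4.0, b=1.1, n_fish=2):
    rows = []
    for f in range(n_fish):
        for act in np.linspace(0.2, 1.6, 8):
            rows.append({"fish_id": f"f{f}", "activity_ms2": act,
                         "speed_ms": act / 2, "mr_mgO2_kg_h": np.exp(log_s + b * act)})
    return pd.DataFrame(rows)


class TestBlockingCorrection:
    def test_no_blockage_limit(self):
        assert bz.blocking_correction(0.5, 0.0, 0.1) == 0.5

    def test_fractional_error_formula(self):
        # area ratio 0.10 with tunnel/shape factor 0.8: speed * 1.0253
        assert bz.blocking_correction(1.0, 0.010, 0.100) == pytest.approx(
            1.025298221281347, rel=1e-9)

    def test_power_law_in_area_ratio(self):
        eps1 = bz.blocking_correction(1.0, 0.01, 0.1) - 1.0
        eps2 = bz.blocking_correction(1.0, 0.02, 0.1) - 1.0
        assert eps2 / eps1 == pytest.approx(2 ** 1.5, rel=1e-9)

    @given(ratio=st.floats(1e-6, 0.5), speed=st.floats(0.05, 2.0))
    def test_correction_inflates_speed(self, ratio, speed):
        corrected = bz.blocking_correction(speed, ratio, 1.0)
        assert corrected > speed

    def test_fish_larger_than_chamber_rejected(self):
        with pytest.raises(ValueError):
            bz.blocking_correction(0.5, 0.2, 0.1)


class TestMassSpecificMR:
    @pytest.mark.parametrize("total, mass, exponent, expected", [
        (100.0, 1000.0, 0.79, 100.0),
        (100.0, 2000.0, 0.79, 57.83440919526437),
        (100.0, 2000.0, 1.0, 50.0),
    ])
    def test_examples(self, total, mass, exponent, expected):
        assert bz.mass_specific_mr(total, mass, exponent) == pytest.approx(
            expected, rel=1e-9)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            bz.mass_specific_mr(100.0, 0.0)


class TestDrawdownReduction:
    def test_known_drawdown(self):
        # 0.2 mg/L over 15 min in 690 L from a 1 kg fish: 552 mgO2/h
        trials = pd.DataFrame([{
            "fish_id": "f1", "stage": 1, "speed_ms": 0.3, "activity_ms2": 0.7,
            "do_mgL_start": 6.9, "do_mgL_end": 6.7, "stage_min": 15.0,
            "mass_g": 1000.0,
        }])
        reduced, excluded = bz.reduce_drawdown(trials)
        assert excluded.empty
        assert reduced["mr_mgO2_kg_h"].iloc[0] == pytest.approx(
            0.2 * 690 / 0.25, rel=1e-9)

    def test_hypoxic_stage_excluded(self):
        trials = pd.DataFrame([
            {"fish_id": "f1", "speed_ms": 0.3, "activity_ms2": 0.7,
             "do_mgL_start": 6.9, "do_mgL_end": 6.5, "stage_min": 15.0,
             "mass_g": 1000.0},
            {"fish_id": "f1", "speed_ms": 0.5, "activity_ms2": 1.0,
             "do_mgL_start": 6.9, "do_mgL_end": 5.0, "stage_min": 15.0,
             "mass_g": 1000.0},
        ])
        reduced, excluded = bz.reduce_drawdown(trials)  # threshold 0.8 * 6.9 = 5.52
        assert len(reduced) == 1 and len(excluded) == 1
        assert (excluded["reason"] == "low_oxygen").all()

    def test_synthetic_drawdown_round_trips(self):
        records = generate_respirometry(seed=3)
        reduced, excluded = bz.reduce_drawdown(
            records.drop(columns=["mr_mgO2_kg_h"]))
        assert excluded.empty
        np.testing.assert_allclose(reduced["mr_mgO2_kg_h"],
                                   records["mr_mgO2_kg_h"], rtol=1e-9)


class TestFitCalibration:
    def test_noiseless_exact_recovery(self):
        fit = bz.fit_calibration(_noiseless_records(), "activity", "exponential")
        assert fit.intercept == pytest.approx(4.0, abs=1e-6)
        assert fit.slope == pytest.approx(1.1, abs=1e-6)
        assert fit.random_intercept_sd == 0.0
        assert fit.predict(0.0) == pytest.approx(np.exp(4.0), rel=1e-6)

    def test_exponential_prediction_positive_at_zero(self):
        records = generate_respirometry(seed=1)
        fit = bz.fit_calibration(records, "activity", "exponential")
        assert fit.predict(0.0) > 0

    def test_single_fish_equals_ols_on_log_scale(self):
        records = generate_respirometry(
            RespirometryScenario(n_fish=1, seed=5))
        fit = bz.fit_calibration(records, "activity", "exponential")
        assert fit.n_groups == 1
        assert any("single fish" in w for w in fit.warnings)
        ols = sm.OLS(np.log(records["mr_mgO2_kg_h"]),
                     sm.add_constant(records["activity_ms2"])).fit()
        assert fit.intercept == pytest.approx(ols.params.iloc[0], abs=1e-6)
        assert fit.slope == pytest.approx(ols.params.iloc[1], abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_parameter_recovery_activity(self, seed):
        sc = RespirometryScenario(seed=seed)
        records = generate_respirometry(sc)
        fit = bz.fit_calibration(records, "activity", "exponential")
        assert abs(fit.slope - sc.true_b) < 0.25
        assert abs(fit.intercept - sc.true_log_s) < 0.3
        assert fit.random_intercept_sd >= 0
        assert fit.residual_sd > 0

    def test_parameter_recovery_speed(self):
        sc = RespirometryScenario(seed=11)
        records = generate_respirometry(sc)
        fit = bz.fit_calibration(records, "speed", "exponential")
        # the speed relationship implied by the activity link
        assert abs(fit.slope - sc.true_z) < 0.35
        assert abs(fit.intercept - sc.true_log_r) < 0.3

    def test_recovery_bias_shrinks_with_noise(self):
        errs = []
        for resid in (0.2, 1e-4):
            sc = RespirometryScenario(seed=2, residual_sd=resid,
                                      random_intercept_sd=0.0,
                                      activity_noise_sd=0.05)
            fit = bz.fit_calibration(generate_respirometry(sc), "activity",
                                     "exponential")
            errs.append(abs(fit.slope - sc.true_b))
        assert errs[1] < errs[0]
        assert errs[1] < 1e-2

    def test_aicc_undefined_for_tiny_sample(self):
        records = _noiseless_records().iloc[:5]
        with pytest.raises(ValueError, match="AICc"):
            bz.fit_calibration(records, "activity", "exponential")

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing column"):
            bz.fit_calibration(pd.DataFrame({"fish_id": []}), "activity")


class TestFormComparison:
    def test_exponential_wins_on_exponential_data(self):
        records = generate_respirometry(seed=0)
        table = bz.compare_forms_aicc(records, "activity")
        assert table["form"].iloc[0] == "exponential"
        assert table["delta_aicc"].iloc[1] > 10

    def test_weights_normalised(self):
        records = generate_respirometry(seed=4)
        table = bz.compare_forms_aicc(records, "activity")
        assert table["akaike_weight"].sum() == pytest.approx(1.0, rel=1e-12)
        assert (table["aicc"].diff().dropna() >= 0).all()

    def test_equal_aicc_gives_equal_weights(self):
        w = akaike_weights([100.0, 100.0])
        np.testing.assert_allclose(w, [0.5, 0.5])
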