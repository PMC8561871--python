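"""Adult-height prediction, biological age and timing classification."""

import numpy as np
import pytest

from bioage.maturation import (
    KRCoefficientTable,
    Timing,
    biological_age,
    classify_timing,
    midparent_height,
    percent_adult_height,
    predict_adult_height,
)


@pytest.fixture
def identity_coeffs():
    return KRCoefficientTable(
        "female", ages=[9.0, 14.0], intercept=[0.0, 0.0],
        beta_stature=[1.0, 1.0], beta_weight=[0.0, 0.0], beta_midparent=[0.0, 0.0],
    )


@pytest.fixture
def two_row_coeffs():
    return KRCoefficientTable(
        "female", ages=[10.0, 12.0], intercept=[10.0, 20.0],
        beta_stature=[0.5, 0.6], beta_weight=[0.1, 0.2], beta_midparent=[0.4, 0.2],
    )


class TestPredictAdultHeight:
    def test_identity_coefficients_return_current_stature(self, identity_coeffs):
        assert predict_adult_height(11.0, 150.0, 40.0, 170.0, identity_coeffs) == 150.0

    def test_hand_linear_combination(self, two_row_coeffs):
        # row at age 10: 10 + 0.5*150 + 0.1*40 + 0.4*170 = 157
        assert predict_adult_height(10.0, 150.0, 40.0, 170.0, two_row_coeffs) == pytest.approx(157.0)

    def test_midpoint_age_equals_mean_of_bracketing_predictions(self, two_row_coeffs):
        lo = predict_adult_height(10.0, 150.0, 40.0, 170.0, two_row_coeffs)
        hi = predict_adult_height(12.0, 150.0, 40.0, 170.0, two_row_coeffs)
        mid = predict_adult_height(11.0, 150.0, 40.0, 170.0, two_row_coeffs)
        assert mid == pytest.approx(0.5 * (lo + hi), rel=1e-12)

    def test_age_outside_span_errors(self, two_row_coeffs):
        with pytest.raises(Exception):
            predict_adult_height(9.0, 150.0, 40.0, 170.0, two_row_coeffs)

    def test_below_current_stature_logs_warning(self, caplog, identity_coeffs):
        shrink = KRCoefficientTable(
            "female", [9.0, 14.0], [0.0, 0.0], [0.5, 0.5], [0.0, 0.0], [0.0, 0.0]
        )
        with caplog.at_level("WARNING", logger="bioage.maturation"):
            predict_adult_height(11.0, 150.0, 40.0, 170.0, shrink)
        assert any("below current stature" in r.message for r in caplog.records)


class TestPercentAdultHeight:
    def test_paper_worked_ratio(self):
        assert percent_adult_height(149.79, 163.7) == pytest.approx(91.5, abs=0.005)

    def test_full_maturity_and_scale_invariance(self):
        assert percent_adult_height(163.7, 163.7) == 100.0
        assert percent_adult_height(75.0, 82.0) == percent_adult_height(150.0, 164.0)

    def test_cap_at_100(self):
        assert percent_adult_height(165.0, 163.7) == 100.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            percent_adult_height(150.0, 0.0)


class TestBiologicalAge:
    def test_worked_example_girl_at_91_5_percent(self, simple_pah):
        """91.5% of adult stature maps to the reference age 12.0."""
        assert biological_age(91.5, simple_pah) == pytest.approx(12.0, abs=1e-12)

    def test_reference_value_at_own_age_is_identity(self, simple_pah):
        pct = simple_pah.percent_at_age(10.5)
        assert biological_age(pct, simple_pah) == pytest.approx(10.5, abs=1e-9)

    def test_forward_inverse_dense_grid(self, simple_pah):
        """Inverse lookup reproduces the forward curve across a dense scan."""
        for pct in np.linspace(81.0, 100.0, 500):
            age = biological_age(pct, simple_pah)
            assert simple_pah.percent_at_age(age) == pytest.approx(pct, abs=1e-9)

    def test_non_decreasing_in_percent(self, pah_female):
        lo, hi = pah_female.percent_span
        pcts = np.linspace(lo, hi, 300)
        ages = pah_female.age_at_percent(pcts)
        assert np.all(np.diff(ages) >= -1e-12)

    def test_flat_segment_resolves_to_youngest_age(self, pah_female):
        # the synthetic curve is flat at 100% from age 18 on
        assert pah_female.age_at_percent(100.0) == pytest.approx(18.0, abs=0.51)


class TestClassifyTiming:
    @pytest.mark.parametrize(
        "chron,bio,expected,offset",
        [
            (10.5, 12.0, Timing.early, 1.5),  # the worked example
            (11.0, 11.0, Timing.on_time, 0.0),
            (11.0, 12.0, Timing.early, 1.0),  # boundary: "1 year or more"
            (12.0, 11.0, Timing.late, -1.0),
            (11.0, 11.99, Timing.on_time, 0.99),
        ],
    )
    def test_rule(self, chron, bio, expected, offset):
        timing, off = classify_timing(chron, bio)
        assert timing is expected
        assert off == pytest.approx(offset)

    def test_antisymmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            a, b = rng.uniform(8, 16, 2)
            t1, o1 = classify_timing(a, b)
            t2, o2 = classify_timing(b, a)
            assert o1 == pytest.approx(-o2)
            assert {Timing.early: Timing.late, Timing.late: Timing.early,
                    Timing.on_time: Timing.on_time}[t1] is t2


def test_midparent_is_arithmetic_mean():
    assert midparent_height(160.0, 180.0) == 170.0
    with pytest.raises(ValueError):
        midparent_height(-1.0, 180.0)


def test_kr_table_csv_round_trip(tmp_path, two_row_coeffs=None):
    table = KRCoefficientTable(
        "male", [10.0, 12.0], [5.0, 6.0], [0.7, 0.8], [-0.02, -0.02], [0.3, 0.3]
    )
    path = tmp_path / "kr.csv"
    table.to_csv(path)
    loaded = KRCoefficientTable.from_csv(path, "male")
    assert np.allclose(loaded.intercept, table.intercept)
    assert np.allclose(loaded.beta_stature, table.beta_stature)
    with pytest.raises(ValueError, match="no coefficient rows"):
        KRCoefficientTable.from_csv(path, "female")
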