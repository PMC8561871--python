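"""LMS transform, percentile engine and percent-of-adult-height curve."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from bioage.reference import (
    AdultStatureNorms,
    AgeOutOfRangeError,
    GrowthReference,
    LMSReferenceTable,
    build_percent_adult_height_reference,
    lms_inverse,
    lms_zscore,
    percentile_to_zscore,
    zscore_to_percentile,
)


@pytest.mark.parametrize(
    "value,L,M,S,expected",
    [
        (20.0, -1.3, 20.0, 0.12, 0.0),  # value at the median
        (22.0, 1.0, 20.0, 0.1, 1.0),  # (22/20 - 1)/0.1
        (20.0 * np.exp(0.1), 0.0, 20.0, 0.1, 1.0),  # log branch
    ],
)
def test_lms_zscore_examples(value, L, M, S, expected):
    assert lms_zscore(value, L, M, S) == pytest.approx(expected, abs=1e-12)


def test_lms_rejects_non_positive_inputs():
    with pytest.raises(ValueError):
        lms_zscore(-1.0, 1.0, 20.0, 0.1)
    with pytest.raises(ValueError):
        lms_zscore(20.0, 1.0, -1.0, 0.1)


@settings(max_examples=200, derandomize=True)
@given(
    L=st.sampled_from([-2.0, 0.0, 1.0, 2.0]),
    M=st.floats(10.0, 200.0),
    S=st.floats(0.02, 0.3),
    z=st.floats(-2.5, 2.5),
)
def test_lms_round_trip(L, M, S, z):
    """value -> z -> value is the identity to 1e-9 relative."""
    assume(1.0 + L * S * z > 0.05)  # inside the distribution's support
    value = lms_inverse(z, L, M, S)
    assert value > 0
    back = lms_inverse(lms_zscore(value, L, M, S), L, M, S)
    assert back == pytest.approx(value, rel=1e-9)


def test_percentile_against_quadrature_oracle():
    """100*Phi(z) checked against direct integration of the normal density."""
    grid = np.linspace(-12.0, 1.6449, 2_000_001)
    dens = np.exp(-grid**2 / 2.0) / np.sqrt(2.0 * np.pi)
    oracle = 100.0 * np.trapezoid(dens, grid)
    assert zscore_to_percentile(1.6449) == pytest.approx(oracle, abs=0.01)
    assert zscore_to_percentile(1.6449) == pytest.approx(95.0, abs=0.01)
    assert zscore_to_percentile(0.0) == 50.0


def test_percentile_round_trip_and_monotonicity():
    zs = np.linspace(-4, 4, 41)
    back = percentile_to_zscore(zscore_to_percentile(zs))
    assert np.allclose(back, zs, atol=1e-6)
    assert np.all(np.diff(zscore_to_percentile(zs)) > 0)


class TestInterpolation:
    @pytest.fixture
    def table(self):
        return LMSReferenceTable(
            "height", "female",
            ages=[10.0, 11.0, 12.0],
            L=[1.0, 1.0, 1.0],
            M=[140.0, 150.0, 156.0],
            S=[0.04, 0.045, 0.05],
        )

    def test_exact_grid_age(self, table):
        assert table.interpolate(11.0) == (1.0, 150.0, 0.045)

    def test_midpoint_linearity(self, table):
        _, M, _ = table.interpolate(10.5)
        assert M == pytest.approx(145.0)

    def test_bracketing_bound_property(self, table):
        rng = np.random.default_rng(7)
        for age in rng.uniform(10.0, 12.0, 200):
            i = np.searchsorted(table.ages, age) - 1
            i = max(0, min(i, len(table.ages) - 2))
            _, M, _ = table.interpolate(float(age))
            assert min(table.M[i], table.M[i + 1]) - 1e-12 <= M <= max(table.M[i], table.M[i + 1]) + 1e-12

    def test_no_extrapolation(self, table):
        with pytest.raises(AgeOutOfRangeError):
            table.interpolate(9.9)
        with pytest.raises(AgeOutOfRangeError):
            table.interpolate(12.1)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            LMSReferenceTable("height", "female", [10.0, 10.0], [1, 1], [140, 141], [0.04, 0.04])
        with pytest.raises(ValueError):
            LMSReferenceTable("height", "female", [10.0, 11.0], [1, 1], [-140, 141], [0.04, 0.04])


class TestPercentAdultHeight:
    def test_paper_anchor_girls_12(self):
        """Median 149.79 cm at 12 over a 163.7 cm adult mean is 91.5%."""
        table = LMSReferenceTable(
            "height", "female", [11.0, 12.0, 18.0], [1, 1, 1],
            [145.0, 149.79, 163.7], [0.04, 0.04, 0.04],
        )
        ref = build_percent_adult_height_reference(table, AdultStatureNorms())
        assert ref.percent_at_age(12.0) == pytest.approx(91.5, abs=0.005)
        assert ref.percent_at_age(18.0) == pytest.approx(100.0)

    def test_rescaling_invariance(self):
        ages = [10.0, 12.0, 18.0]
        M = np.array([130.0, 150.0, 163.7])
        t1 = LMSReferenceTable("height", "female", ages, [1] * 3, M, [0.04] * 3)
        t2 = LMSReferenceTable("height", "female", ages, [1] * 3, M * 1.1, [0.04] * 3)
        n1 = AdultStatureNorms(177.6, 163.7)
        n2 = AdultStatureNorms(177.6 * 1.1, 163.7 * 1.1)
        r1 = build_percent_adult_height_reference(t1, n1)
        r2 = build_percent_adult_height_reference(t2, n2)
        assert np.allclose(r1.percents, r2.percents)

    def test_monotone_median_gives_monotone_percent(self, reference, norms):
        ref = reference.percent_adult_height("male", norms)
        assert np.all(np.diff(ref.percents) >= -1e-12)

    def test_inverse_lookup_out_of_range_reports_boundary(self, simple_pah):
        with pytest.raises(AgeOutOfRangeError, match="boundary age"):
            simple_pah.age_at_percent(50.0)
        with pytest.raises(AgeOutOfRangeError, match="boundary age"):
            simple_pah.age_at_percent(100.5)


def test_growth_reference_csv_round_trip(tmp_path, reference):
    path = tmp_path / "ref.csv"
    reference.to_csv(path)
    loaded = GrowthReference.from_csv(path)
    for meas in ("height", "bmi"):
        for sex in ("male", "female"):
            a, b = reference.table(meas, sex), loaded.table(meas, sex)
            assert np.allclose(a.ages, b.ages)
            assert np.allclose(a.M, b.M)
            assert np.allclose(a.L, b.L)
            assert np.allclose(a.S, b.S)


def test_growth_reference_missing_columns(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("measurement,sex,age_years,L,M\nheight,male,10,1,140\n")
    with pytest.raises(ValueError, match="missing columns"):
        GrowthReference.from_csv(p)
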