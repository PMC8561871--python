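"""Contingency statistics, multinomial fits, criteria and odds ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioage.models import (
    ConvergenceError,
    DegenerateTableError,
    ModelFit,
    TransitionTable,
    apply_dispersion_scaling,
    compare_models,
    fit_multinomial,
    odds_ratio_2x2,
    pearson_chi2,
    row_percentages,
)

# age-11 -> age-17 transition counts for the chronological and biological
# matching schemes (healthy / overweight / obese)
CHRON_COUNTS = [[963, 85, 17], [79, 50, 33], [38, 30, 98]]
BIO_COUNTS = [[990, 101, 26], [76, 46, 46], [15, 18, 76]]
LABELS = ("healthy", "overweight", "obese")


def brute_force_chi2(counts):
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    stat = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            e = counts[i].sum() * counts[:, j].sum() / total
            stat += (counts[i, j] - e) ** 2 / e
    return stat


class TestPearsonChi2:
    def test_transition_counts(self):
        stat, dof = pearson_chi2(TransitionTable(LABELS, LABELS, CHRON_COUNTS))
        assert dof == 4
        assert stat == pytest.approx(brute_force_chi2(CHRON_COUNTS), rel=1e-12)
        assert stat == pytest.approx(634, rel=0.01)

    def test_proportional_rows_give_zero(self):
        stat, _ = pearson_chi2(TransitionTable(("a", "b"), ("x", "y"), [[10, 20], [30, 60]]))
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_hand_value(self):
        stat, dof = pearson_chi2(TransitionTable(("a", "b"), ("x", "y"), [[10, 0], [0, 10]]))
        assert (stat, dof) == (pytest.approx(20.0), 1)

    def test_zero_margin_errors(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi2(TransitionTable(("a", "b"), ("x", "y"), [[0, 10], [0, 10]]))

    @settings(max_examples=150, derandomize=True)
    @given(
        r=st.integers(2, 4),
        c=st.integers(2, 4),
        seed=st.integers(0, 10_000),
    )
    def test_matches_brute_force_oracle(self, r, c, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 50, size=(r, c))
        table = TransitionTable(tuple(map(str, range(r))), tuple(map(str, range(c))), counts)
        stat, dof = pearson_chi2(table)
        assert stat == pytest.approx(brute_force_chi2(counts), rel=1e-10)
        assert dof == (r - 1) * (c - 1)


class TestRowPercentages:
    def test_obese_row(self):
        pct = row_percentages(TransitionTable(LABELS, LABELS, CHRON_COUNTS))
        assert list(pct[2]) == [23, 18, 59]

    def test_biological_obese_row(self):
        pct = row_percentages(TransitionTable(LABELS, LABELS, BIO_COUNTS))
        assert list(pct[2]) == [14, 17, 70]

    def test_single_cell_row(self):
        pct = row_percentages(TransitionTable(("a", "b"), ("x", "y"), [[7, 0], [1, 1]]))
        assert pct[0, 0] == 100

    def test_zero_row_blank(self):
        pct = row_percentages(TransitionTable(("a", "b"), ("x", "y"), [[0, 0], [1, 1]]))
        assert np.isnan(pct[0]).all()


def binary_frame(counts):
    """Rows: exposure 1/0; columns: outcome yes/no."""
    rows = []
    for x, (yes, no) in zip((1.0, 0.0), counts):
        rows += [{"x": x, "y": "yes"}] * yes + [{"x": x, "y": "no"}] * no
    return pd.DataFrame(rows)


class TestFitMultinomial:
    def test_closed_form_contingency_coefficient(self):
        data = binary_frame([[40, 10], [20, 30]])
        fit = fit_multinomial(data, "y", "x", reference_level="no")
        coef = fit.params.loc["x", "yes vs no"]
        assert coef == pytest.approx(np.log(6.0), abs=1e-6)
        ors = fit.odds_ratios()
        assert ors.loc[ors["term"] == "x", "odds_ratio"].iloc[0] == pytest.approx(6.0, rel=1e-5)

    def test_independent_predictor_has_zero_coefficient(self):
        data = binary_frame([[25, 25], [25, 25]])
        fit = fit_multinomial(data, "y", "x", reference_level="no")
        assert fit.params.loc["x", "yes vs no"] == pytest.approx(0.0, abs=1e-8)

    def test_two_level_fit_matches_binary_logit(self):
        """Multinomial with two outcome levels equals an independent
        binary-logit fit on the same data, coefficient by coefficient."""
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        n = 800
        x1 = rng.normal(size=n)
        x2 = rng.integers(0, 2, n).astype(float)
        eta = -0.3 + 0.8 * x1 - 0.5 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        data = pd.DataFrame({"x1": x1, "x2": x2, "y": np.where(y == 1, "case", "ctrl")})
        fit = fit_multinomial(data, "y", "x1 + x2", reference_level="ctrl")
        logit = sm.Logit(y, sm.add_constant(np.column_stack([x1, x2]))).fit(disp=False)
        assert np.allclose(
            fit.params["case vs ctrl"].to_numpy(), logit.params, atol=1e-6
        )

    def test_ordinal_parameter_recovery(self):
        """A known +1.2 log-odds per category step is recovered at n=5000."""
        rng = np.random.default_rng(42)
        n = 5000
        x = rng.integers(0, 3, n).astype(float)
        eta = -1.5 + 1.2 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        data = pd.DataFrame({"x": x, "y": np.where(y == 1, "hi", "lo")})
        fit = fit_multinomial(data, "y", "x", reference_level="lo")
        assert fit.params.loc["x", "hi vs lo"] == pytest.approx(1.2, abs=0.1)

    def test_information_criteria_identities(self, default_analysis):
        for fit in default_analysis.models["fits"].values():
            assert fit.aic == pytest.approx(2 * fit.k_params - 2 * fit.llf, abs=1e-9)
            assert fit.bic == pytest.approx(
                fit.k_params * np.log(fit.n_obs) - 2 * fit.llf, abs=1e-9
            )
            assert fit.dispersion > 0

    def test_intercept_only_percent_correct_equals_majority_rate(self):
        data = binary_frame([[40, 10], [20, 30]])
        fit = fit_multinomial(data, "y", "1", reference_level="no")
        majority = 100.0 * max((data["y"] == "yes").mean(), (data["y"] == "no").mean())
        assert fit.percent_correct == pytest.approx(majority)

    def test_missing_outcome_column(self):
        with pytest.raises(ValueError, match="outcome column"):
            fit_multinomial(pd.DataFrame({"x": [1.0, 2.0]}), "y", "x")


def make_fit(label="m", llf=-100.0, n=100, k=4, outcome="y", levels=("a", "b")):
    frame = pd.DataFrame({"b vs a": [0.5] * k}, index=[f"p{i}" for i in range(k)])
    return ModelFit(
        label=label, outcome=outcome, outcome_levels=tuple(levels),
        reference_level=levels[0], formula_rhs="x", params=frame,
        se=frame.copy(), llf=llf, n_obs=n, k_params=k,
        percent_correct=50.0, converged=True,
    )


class TestDispersionScaling:
    def test_phi_one_leaves_se_unchanged(self):
        # deviance = df_resid  =>  phi = 1
        fit = make_fit(llf=-0.5 * (100 - 4), n=100, k=4)
        scaled = apply_dispersion_scaling(fit)
        assert scaled.dispersion == pytest.approx(1.0)
        assert np.allclose(scaled.se, fit.se)

    def test_phi_four_doubles_se(self):
        fit = make_fit(llf=-2.0 * (100 - 4), n=100, k=4)
        scaled = apply_dispersion_scaling(fit)
        assert scaled.dispersion == pytest.approx(4.0)
        assert np.allclose(scaled.se, 2.0 * fit.se)
        assert np.allclose(scaled.params, fit.params)  # coefficients untouched

    def test_overdispersed_binary_groups_detected(self):
        """Extra-binomial variation inflates phi above 1."""
        rng = np.random.default_rng(8)
        n = 400
        # cluster-level random intercepts induce overdispersion
        cluster_p = rng.beta(2, 2, size=n)
        y = (rng.random(n) < cluster_p).astype(int)
        data = pd.DataFrame({"y": np.where(y == 1, "hi", "lo")})
        fit = fit_multinomial(data, "y", "1", reference_level="lo")
        assert fit.dispersion > 1.0


class TestCompareModels:
    def test_identical_fits_equivalent(self):
        a = make_fit("a")
        b = make_fit("b")
        comp = compare_models(a, b)
        assert comp.delta_bic == 0.0
        assert comp.verdict == "equivalent"

    def test_small_delta_is_equivalent(self):
        a = make_fit("a", llf=-100.0)
        b = make_fit("b", llf=-100.75)  # dBIC = 1.5
        comp = compare_models(a, b)
        assert comp.delta_bic == pytest.approx(1.5)
        assert comp.verdict == "equivalent"

    def test_meaningful_difference_names_winner(self):
        a = make_fit("chron", llf=-110.0)
        b = make_fit("bio", llf=-100.0)
        comp = compare_models(a, b)
        assert comp.delta_bic == pytest.approx(-20.0)
        assert "bio" in comp.verdict and "better" in comp.verdict

    def test_different_samples_incomparable(self):
        with pytest.raises(ValueError, match="different samples"):
            compare_models(make_fit(n=100), make_fit(n=101))
        with pytest.raises(ValueError, match="different outcomes"):
            compare_models(make_fit(outcome="y"), make_fit(outcome="z"))


class TestOddsRatio:
    def test_closed_form(self):
        res = odds_ratio_2x2([[40, 10], [20, 30]])
        assert res.odds_ratio == pytest.approx(6.0)
        assert res.ci_low < 6.0 < res.ci_high

    def test_identical_rows_give_unity(self):
        assert odds_ratio_2x2([[15, 30], [15, 30]]).odds_ratio == pytest.approx(1.0)

    def test_zero_cell_continuity_correction(self):
        res = odds_ratio_2x2([[10, 0], [5, 5]])
        assert res.continuity_corrected
        assert np.isfinite(res.odds_ratio)
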