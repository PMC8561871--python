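"""Regression models, information criteria and contingency statistics.

Weight status at the first visit (as an ordinal BMI category score)
predicts (a) the BMI category and (b) the dichotomised cardiometabolic
risk at the second visit, via maximum-likelihood multinomial logistic
regression with sex, ethnicity and maternal socio-economic group as
covariates.  Competing classification schemes (chronological vs.
biologically adjusted) are compared on the same outcome and sample via
AIC/BIC; |dBIC| < 2 is treated as equivalent fit.  Deviance dispersion
scaling (phi = deviance / residual df) inflates standard errors to
absorb overdispersion without touching coefficients or the criteria.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import patsy
from scipy.stats import chi2_contingency, norm
from statsmodels.discrete.discrete_model import MNLogit

__all__ = [
    "DegenerateTableError",
    "ConvergenceError",
    "TransitionTable",
    "pearson_chi2",
    "row_percentages",
    "ModelFit",
    "fit_multinomial",
    "apply_dispersion_scaling",
    "ModelComparison",
    "compare_models",
    "OddsRatio",
    "odds_ratio_2x2",
    "maturity_odds",
]

logger = logging.getLogger(__name__)

#: |dBIC| below which two fits count as equivalent
BIC_EQUIVALENCE = 2.0


class DegenerateTableError(ValueError):
    """Contingency table with an empty margin."""


class ConvergenceError(RuntimeError):
    """The likelihood optimiser failed to converge (possible separation)."""


@dataclass(frozen=True)
class TransitionTable:
    """Cross-tabulation of a category at visit 1 against visit 2."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("transition table must be at least 2x2")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            counts = counts.astype(float)
            if np.any(counts < 0) or np.any(counts != np.round(counts)):
                raise ValueError("counts must be non-negative integers")
            counts = counts.astype(int)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))
        if len(self.row_labels) != counts.shape[0] or len(self.col_labels) != counts.shape[1]:
            raise ValueError("labels must match the count matrix shape")

    @classmethod
    def from_categories(cls, first, second, labels) -> "TransitionTable":
        first = pd.Categorical(first, categories=labels)
        second = pd.Categorical(second, categories=labels)
        counts = pd.crosstab(first, second, dropna=False).reindex(
            index=labels, columns=labels, fill_value=0
        )
        return cls(tuple(labels), tuple(labels), counts.to_numpy())

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels), columns=list(self.col_labels))


def pearson_chi2(table: TransitionTable) -> tuple[float, int]:
    """Pearson chi-square statistic and df = (r-1)(c-1) for a table."""
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise DegenerateTableError("table has an empty row or column margin")
    stat, _, dof, _ = chi2_contingency(counts, correction=False)
    return float(stat), int(dof)


def row_percentages(table: TransitionTable, as_int: bool = True) -> np.ndarray:
    """Cells as percent of their row sum.

    With ``as_int`` (report layout) percentages are rounded to whole
    numbers; rows summing to zero yield NaN (rendered blank).
    """
    counts = table.counts.astype(float)
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * counts / sums
    pct[np.repeat(sums == 0, counts.shape[1], axis=1)] = np.nan
    if as_int:
        return np.where(np.isnan(pct), np.nan, np.round(pct))
    return pct


@dataclass(frozen=True)
class ModelFit:
    """A fitted multinomial logistic model and its summary quantities.

    ``params`` and ``se`` are frames with one row per design column and
    one column per non-reference outcome level.  ``deviance`` is
    -2 log L (ungrouped data), ``dispersion`` deviance / residual df
    with residual df = n*(J-1) - k.
    """

    label: str
    outcome: str
    outcome_levels: tuple[str, ...]
    reference_level: str
    formula_rhs: str
    params: pd.DataFrame
    se: pd.DataFrame
    llf: float
    n_obs: int
    k_params: int
    percent_correct: float
    converged: bool
    se_scaled: bool = False

    @property
    def deviance(self) -> float:
        return -2.0 * self.llf

    @property
    def df_resid(self) -> int:
        return self.n_obs * (len(self.outcome_levels) - 1) - self.k_params

    @property
    def dispersion(self) -> float:
        return self.deviance / self.df_resid

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.llf

    @property
    def bic(self) -> float:
        return self.k_params * np.log(self.n_obs) - 2.0 * self.llf

    def odds_ratios(self, level: float = 0.95) -> pd.DataFrame:
        """exp(coefficients) with Wald confidence intervals.

        Intervals use the stored standard errors, so dispersion scaling
        (if applied) widens them.
        """
        z = norm.ppf(0.5 + level / 2.0)
        rows = []
        for contrast in self.params.columns:
            for name in self.params.index:
                b = self.params.loc[name, contrast]
                s = self.se.loc[name, contrast]
                rows.append(
                    {
                        "contrast": contrast,
                        "term": name,
                        "odds_ratio": np.exp(b),
                        "ci_low": np.exp(b - z * s),
                        "ci_high": np.exp(b + z * s),
                    }
                )
        return pd.DataFrame(rows)


def fit_multinomial(
    data: pd.DataFrame,
    outcome: str,
    formula_rhs: str,
    reference_level: str | None = None,
    label: str | None = None,
    maxiter: int = 200,
) -> ModelFit:
    """Fit a multinomial logit of ``outcome`` on a patsy RHS formula.

    The outcome column may be any categorical/string series; its first
    observed level (or ``reference_level``) becomes the reference
    against which the per-level log-odds are expressed.  Separation or
    non-convergence raises :class:`ConvergenceError` rather than
    returning silent output.
    """
    if outcome not in data.columns:
        raise ValueError(f"outcome column {outcome!r} not in data")
    y_raw = pd.Series(data[outcome]).astype(str)
    levels = list(pd.unique(y_raw))
    if reference_level is not None:
        if reference_level not in levels:
            raise ValueError(f"reference level {reference_level!r} not among outcome levels {levels}")
        levels = [reference_level] + sorted(l for l in levels if l != reference_level)
    else:
        levels = sorted(levels)
    if len(levels) < 2:
        raise ValueError("outcome needs at least 2 levels")
    codes = y_raw.map({l: i for i, l in enumerate(levels)}).to_numpy()

    exog = patsy.dmatrix(formula_rhs, data, return_type="dataframe")
    if len(exog) != len(data):
        raise ValueError("predictors contain missing values; complete-case filter the data first")
    # inestimable cells: a design column that is identically zero
    dead = [c for c in exog.columns if np.allclose(exog[c], 0.0)]
    if dead:
        raise ValueError(f"empty predictor cells make the fit inestimable: {dead}")

    model = MNLogit(codes, exog.to_numpy())
    result = None
    with np.errstate(over="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method, iters in (("newton", maxiter), ("lbfgs", 10 * maxiter)):
            try:
                candidate = model.fit(method=method, maxiter=iters, disp=False, full_output=True)
            except np.linalg.LinAlgError:
                continue
            if candidate.mle_retvals.get("converged", False):
                result = candidate
                break
    if result is None:
        raise ConvergenceError(
            f"multinomial fit did not converge in {maxiter} iterations "
            "(check for separation or empty predictor cells)"
        )
    if np.any(np.abs(result.params) > 30):
        logger.warning("very large coefficients detected; data may be quasi-separated")

    contrast_names = [f"{lvl} vs {levels[0]}" for lvl in levels[1:]]
    params = pd.DataFrame(result.params, index=exog.columns, columns=contrast_names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # nan SE under quasi-separation
        se = pd.DataFrame(result.bse, index=exog.columns, columns=contrast_names)
    probs = result.predict()
    predicted = np.argmax(probs, axis=1)
    percent_correct = 100.0 * float(np.mean(predicted == codes))
    k = params.size

    return ModelFit(
        label=label or f"{outcome} ~ {formula_rhs}",
        outcome=outcome,
        outcome_levels=tuple(levels),
        reference_level=levels[0],
        formula_rhs=formula_rhs,
        params=params,
        se=se,
        llf=float(result.llf),
        n_obs=int(len(data)),
        k_params=int(k),
        percent_correct=percent_correct,
        converged=True,
    )


def apply_dispersion_scaling(fit: ModelFit) -> ModelFit:
    """Scale standard errors by sqrt(deviance / residual df).

    Coefficients, log-likelihood and the information criteria are left
    untouched; only the uncertainty (and hence the confidence
    intervals) widens when phi > 1.
    """
    if fit.df_resid <= 0:
        raise ValueError("dispersion scaling requires positive residual df")
    phi = fit.dispersion
    return replace(fit, se=fit.se * np.sqrt(phi), se_scaled=True)


@dataclass(frozen=True)
class ModelComparison:
    label_a: str
    label_b: str
    delta_aic: float
    delta_bic: float  # BIC_b - BIC_a
    verdict: str  # "equivalent" or "<label> meaningfully better"


def compare_models(fit_a: ModelFit, fit_b: ModelFit) -> ModelComparison:
    """AIC/BIC comparison of two fits of the same outcome on the same sample."""
    if fit_a.outcome_levels != fit_b.outcome_levels or fit_a.outcome != fit_b.outcome:
        raise ValueError("models predict different outcomes; comparison undefined")
    if fit_a.n_obs != fit_b.n_obs:
        raise ValueError(
            f"models fit different samples (n={fit_a.n_obs} vs n={fit_b.n_obs})"
        )
    delta_bic = fit_b.bic - fit_a.bic
    delta_aic = fit_b.aic - fit_a.aic
    if abs(delta_bic) < BIC_EQUIVALENCE:
        verdict = "equivalent"
    elif delta_bic > 0:
        verdict = f"{fit_a.label} meaningfully better"
    else:
        verdict = f"{fit_b.label} meaningfully better"
    return ModelComparison(fit_a.label, fit_b.label, float(delta_aic), float(delta_bic), verdict)


@dataclass(frozen=True)
class OddsRatio:
    odds_ratio: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool = False


def odds_ratio_2x2(table, level: float = 0.95) -> OddsRatio:
    """Contingency odds ratio (ad/bc) with a Woolf log-scale interval.

    ``table`` is [[exposed & case, exposed & non-case], [unexposed &
    case, unexposed & non-case]].  A zero cell triggers the Haldane
    correction (0.5 added to every cell) with a warning.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("expected a non-negative 2x2 table")
    corrected = False
    if np.any(t == 0):
        logger.warning("zero cell in 2x2 table; applying 0.5 continuity correction")
        t = t + 0.5
        corrected = True
    a, b = t[0]
    c, d = t[1]
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(0.5 + level / 2.0)
    return OddsRatio(
        odds_ratio=float(or_),
        ci_low=float(np.exp(np.log(or_) - z * se)),
        ci_high=float(np.exp(np.log(or_) + z * se)),
        continuity_corrected=corrected,
    )


def maturity_odds(
    cohort: pd.DataFrame,
    timing_column: str = "timing",
    outcome_mask=None,
    category_column: str = "category_chron_v1",
    positive_categories=("overweight", "obese"),
) -> OddsRatio:
    """Odds of overweight/obesity for early vs. non-early maturers.

    The exposure is ``timing == "early"``; the outcome defaults to
    membership of ``positive_categories`` in ``category_column`` but an
    explicit boolean ``outcome_mask`` can be supplied instead.
    """
    if timing_column not in cohort.columns:
        raise ValueError(f"cohort lacks timing column {timing_column!r}")
    exposed = (cohort[timing_column] == "early").to_numpy()
    if outcome_mask is None:
        if category_column not in cohort.columns:
            raise ValueError(f"cohort lacks category column {category_column!r}")
        case = cohort[category_column].isin(positive_categories).to_numpy()
    else:
        case = np.asarray(outcome_mask, dtype=bool)
    table = [
        [int(np.sum(exposed & case)), int(np.sum(exposed & ~case))],
        [int(np.sum(~exposed & case)), int(np.sum(~exposed & ~case))],
    ]
    return odds_ratio_2x2(table)
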