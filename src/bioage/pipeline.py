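"""End-to-end analysis: classify, score, model, report.

Given a two-visit cohort table and growth references, the pipeline

1. assesses each child's maturity at both visits (predicted adult
   height, percent attained, biological age, timing class),
2. classifies weight status under chronological and biological
   matching at both visits,
3. excludes underweight children (chronological screening at visit 1)
   and incomplete cases, keeping an explicit exclusion log,
4. computes the composite cardiometabolic risk score and median split,
5. fits the prediction models for both outcomes under both
   classification schemes, applies dispersion scaling, and compares
   schemes by AIC/BIC, plus two interaction models (timing x BMI
   category and timing x sex, covariates dropped for parsimony),
6. writes a Table-1-style description, Table-3-style transition
   tables with chi-square statistics, and a machine-readable results
   file.

Every child in the input ends up exactly once in either the modelling
set or the exclusion log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cardiometabolic as cm
from .maturation import KRCoefficientTable, classify_timing, percent_adult_height, predict_adult_height
from .models import (
    ConvergenceError,
    ModelComparison,
    ModelFit,
    TransitionTable,
    apply_dispersion_scaling,
    compare_models,
    fit_multinomial,
    maturity_odds,
    pearson_chi2,
    row_percentages,
)
from .reference import AdultStatureNorms, GrowthReference, Sex
from .simulate import COHORT_COLUMNS
from .synthetic_reference import synthetic_adult_norms, synthetic_growth_reference, synthetic_kr_table
from .weight import DEFAULT_CUTOFFS, ORDINAL_SCORE, WeightCategory, categorize, exclude_underweight

__all__ = [
    "SchemaError",
    "RunConfig",
    "classify_cohort",
    "descriptives",
    "transition_analysis",
    "fit_outcome_models",
    "run_analysis",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

MODEL_CATEGORIES = ["healthy", "overweight", "obese"]


class SchemaError(ValueError):
    """Input table does not match the expected column schema."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    cohort_path: str | None = None
    reference_path: str | None = None  # None -> built-in synthetic reference
    kr_path: str | None = None
    output_dir: str = "bioage_output"
    adult_height_male: float = 177.6
    adult_height_female: float = 163.7
    cutoffs: tuple = DEFAULT_CUTOFFS
    timing_threshold: float = 1.0
    month_binning: bool = False
    sex_stratified_z: bool = False
    seed: int = 0

    def __post_init__(self):
        u, o, b = self.cutoffs
        if not 0 < u < o < b < 100:
            raise ValueError("cut-offs must be strictly increasing in (0, 100)")
        if self.timing_threshold <= 0:
            raise ValueError("timing threshold must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cutoffs" in raw:
            raw["cutoffs"] = tuple(raw["cutoffs"])
        return cls(**raw)

    def norms(self) -> AdultStatureNorms:
        return AdultStatureNorms(self.adult_height_male, self.adult_height_female)


def validate_cohort(cohort: pd.DataFrame) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort table missing column(s): {missing}")


def _load_references(config: RunConfig):
    norms = config.norms()
    if config.reference_path:
        reference = GrowthReference.from_csv(config.reference_path)
    else:
        reference = synthetic_growth_reference(norms)
    if config.kr_path:
        kr = {s: KRCoefficientTable.from_csv(config.kr_path, s) for s in (Sex.male, Sex.female)}
    else:
        kr = {s: synthetic_kr_table(s, reference, norms) for s in (Sex.male, Sex.female)}
    return reference, norms, kr


def classify_cohort(
    cohort: pd.DataFrame,
    reference: GrowthReference | None = None,
    norms: AdultStatureNorms | None = None,
    kr_tables: dict | None = None,
    cutoffs=DEFAULT_CUTOFFS,
    timing_threshold: float = 1.0,
    month_binning: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-child maturity and weight classification at both visits.

    Returns ``(classified, excluded)``; the exclusion log carries one
    row per dropped child with a ``reason`` column (missing modelling
    variables, non-positive measurements, or ages/percents outside the
    reference span).  Underweight exclusion is a separate later step.
    """
    validate_cohort(cohort)
    norms = norms or synthetic_adult_norms()
    reference = reference or synthetic_growth_reference(norms)
    if kr_tables is None:
        kr_tables = {s: synthetic_kr_table(s, reference, norms) for s in (Sex.male, Sex.female)}

    df = cohort.reset_index(drop=True).copy()
    reasons = pd.Series("", index=df.index, dtype=object)

    value_cols = [c for c in COHORT_COLUMNS if c not in ("id", "sex", "ethnicity", "ses")]
    na_mask = df[value_cols].isna().any(axis=1) | df[["sex", "ethnicity", "ses"]].isna().any(axis=1)
    reasons[na_mask] = "missing modelling variable"

    pos_cols = ["height_v1", "weight_v1", "height_v2", "weight_v2", "mother_height", "father_height"]
    nonpos = ~na_mask & (df[pos_cols].le(0).any(axis=1))
    reasons[nonpos] = "non-positive measurement"

    bad_sex = (reasons == "") & ~df["sex"].isin([Sex.male.value, Sex.female.value])
    reasons[bad_sex] = "unknown sex code"

    out_cols = {
        "bmi_v1": np.nan, "bmi_v2": np.nan,
        "predicted_adult_height": np.nan, "percent_adult_height": np.nan,
        "biological_age_v1": np.nan, "maturity_offset": np.nan, "timing": "",
        "biological_age_v2": np.nan,
        "pct_chron_v1": np.nan, "pct_bio_v1": np.nan,
        "pct_chron_v2": np.nan, "pct_bio_v2": np.nan,
    }
    for c, v in out_cols.items():
        df[c] = v

    for s in (Sex.male, Sex.female):
        mask = (reasons == "") & (df["sex"] == s.value)
        if not mask.any():
            continue
        idx = df.index[mask]
        height_tab = reference.height(s)
        bmi_tab = reference.bmi(s)
        pah = reference.percent_adult_height(s, norms)
        kr = kr_tables[s]
        lo = max(height_tab.age_span[0], kr.age_span[0], bmi_tab.age_span[0])
        hi = min(height_tab.age_span[1], kr.age_span[1], bmi_tab.age_span[1])

        for visit in ("v1", "v2"):
            age = df.loc[idx, f"age_{visit}"].to_numpy(dtype=float)
            ok = (age >= lo) & (age <= hi)
            bad_idx = idx[~ok]
            reasons[bad_idx] = f"age_{visit} outside reference span"
            idx = idx[ok]
            if idx.empty:
                break
        if idx.empty:
            continue

        plo, phi = pah.percent_span
        for visit in ("v1", "v2"):
            age = df.loc[idx, f"age_{visit}"].to_numpy(dtype=float)
            h = df.loc[idx, f"height_{visit}"].to_numpy(dtype=float)
            w = df.loc[idx, f"weight_{visit}"].to_numpy(dtype=float)
            mp = 0.5 * (
                df.loc[idx, "mother_height"].to_numpy(dtype=float)
                + df.loc[idx, "father_height"].to_numpy(dtype=float)
            )
            pred = predict_adult_height(age, h, w, mp, kr)
            pct = percent_adult_height(h, pred)
            in_range = pct >= plo - 1e-9
            reasons[idx[~in_range]] = f"percent of adult height below reference at {visit}"
            idx = idx[in_range]
            if idx.empty:
                break
            age = age[in_range]
            h = h[in_range]
            w = w[in_range]
            pred = pred[in_range]
            pct = np.minimum(pct[in_range], phi)
            bio = pah.age_at_percent(pct)
            bmi = w / (h / 100.0) ** 2
            match_chron = np.round(age * 12) / 12 if month_binning else age
            match_bio = np.round(bio * 12) / 12 if month_binning else bio
            df.loc[idx, f"bmi_{visit}"] = bmi
            df.loc[idx, f"biological_age_{visit}"] = bio
            tiny = np.nextafter(0.0, 1.0)
            top = np.nextafter(100.0, 0.0)
            df.loc[idx, f"pct_chron_{visit}"] = np.clip(
                bmi_tab.percentile(bmi, np.clip(match_chron, lo, hi)), tiny, top
            )
            df.loc[idx, f"pct_bio_{visit}"] = np.clip(
                bmi_tab.percentile(bmi, np.clip(match_bio, lo, hi)), tiny, top
            )
            if visit == "v1":
                df.loc[idx, "predicted_adult_height"] = pred
                df.loc[idx, "percent_adult_height"] = pct
                timing, offset = classify_timing(age, bio, timing_threshold)
                df.loc[idx, "maturity_offset"] = offset
                df.loc[idx, "timing"] = np.atleast_1d(timing)

    keep = reasons == ""
    classified = df[keep].copy()
    for visit in ("v1", "v2"):
        for scheme in ("chron", "bio"):
            classified[f"category_{scheme}_{visit}"] = categorize(
                classified[f"pct_{scheme}_{visit}"].to_numpy(dtype=float), cutoffs
            )
    excluded = cohort.reset_index(drop=True)[~keep.to_numpy()].copy()
    excluded["reason"] = reasons[~keep].to_numpy()
    if len(excluded):
        logger.info("excluded %d of %d children: %s", len(excluded), len(cohort),
                    excluded["reason"].value_counts().to_dict())
    return classified, excluded


def descriptives(classified: pd.DataFrame) -> dict:
    """Table-1-style summary: ages, BMI, category counts, timing shares."""
    out: dict = {"n": int(len(classified))}
    for s in ("male", "female"):
        sub = classified[classified["sex"] == s]
        block = {
            "n": int(len(sub)),
            "age_v1_mean": float(sub["age_v1"].mean()),
            "age_v1_sd": float(sub["age_v1"].std()),
            "bmi_v1_mean": float(sub["bmi_v1"].mean()),
            "bmi_v1_sd": float(sub["bmi_v1"].std()),
            "percent_adult_height_mean": float(sub["percent_adult_height"].mean()),
        }
        for scheme in ("chron", "bio"):
            counts = sub[f"category_{scheme}_v1"].value_counts()
            block[f"categories_{scheme}_v1"] = {
                c.value: int(counts.get(c.value, 0)) for c in WeightCategory
            }
        timing = sub["timing"].value_counts()
        block["timing"] = {t: int(timing.get(t, 0)) for t in ("early", "on_time", "late")}
        out[s] = block
    return out


def _merged_category(series: pd.Series) -> pd.Series:
    """Underweight folded into healthy (outcome/transition layout)."""
    return series.replace({WeightCategory.underweight.value: WeightCategory.healthy.value})


def transition_analysis(modelling: pd.DataFrame) -> dict:
    """Scheme-specific 3x3 visit-1 x visit-2 transitions with chi-square."""
    out = {}
    for scheme in ("chron", "bio"):
        first = _merged_category(modelling[f"category_{scheme}_v1"])
        second = _merged_category(modelling[f"category_{scheme}_v2"])
        table = TransitionTable.from_categories(first, second, MODEL_CATEGORIES)
        stat, dof = pearson_chi2(table)
        out[scheme] = {
            "table": table,
            "chi2": stat,
            "df": dof,
            "row_percent": row_percentages(table),
        }
    return out


def fit_outcome_models(modelling: pd.DataFrame) -> dict:
    """The four main fits, two scheme comparisons and two interaction fits.

    Outcomes: the chronological age-17 BMI category (underweight merged
    into healthy) and the high/low cardiometabolic risk class; both are
    modelled from the ordinal age-11 BMI category under each scheme
    with sex, ethnicity and maternal SES as covariates.  Outcomes are
    shared across schemes so BIC values are directly comparable.
    """
    data = modelling.copy()
    data["bmi17_category"] = _merged_category(data["category_chron_v2"]).astype(str)
    for scheme in ("chron", "bio"):
        data[f"bmi_ord_{scheme}"] = (
            _merged_category(data[f"category_{scheme}_v1"]).map(ORDINAL_SCORE).astype(float)
        )

    covariates = "C(sex) + C(ethnicity) + C(ses)"
    fits: dict[str, ModelFit] = {}
    comparisons: dict[str, ModelComparison] = {}
    for outcome, ref in (("bmi17_category", "healthy"), ("cmr_class", "low")):
        for scheme in ("chron", "bio"):
            fit = fit_multinomial(
                data,
                outcome=outcome,
                formula_rhs=f"bmi_ord_{scheme} + {covariates}",
                reference_level=ref,
                label=f"{outcome}~{scheme}",
            )
            fits[f"{outcome}_{scheme}"] = apply_dispersion_scaling(fit)
        comparisons[outcome] = compare_models(
            fits[f"{outcome}_chron"], fits[f"{outcome}_bio"]
        )

    interaction_rhs = "bmi_ord_bio * C(timing) + C(timing) * C(sex)"
    interactions: dict = {}
    for outcome, ref in (("bmi17_category", "healthy"), ("cmr_class", "low")):
        try:
            interactions[outcome] = apply_dispersion_scaling(
                fit_multinomial(
                    data,
                    outcome=outcome,
                    formula_rhs=interaction_rhs,
                    reference_level=ref,
                    label=f"{outcome}~interaction",
                )
            )
        except (ValueError, ConvergenceError) as exc:
            # sparse timing-by-category cells can make interaction terms
            # inestimable in small cohorts; report rather than abort the run
            logger.warning("interaction model for %s not estimable: %s", outcome, exc)
            interactions[outcome] = str(exc)
    return {"fits": fits, "comparisons": comparisons, "interactions": interactions}


@dataclass
class AnalysisResults:
    descriptives: dict
    transitions: dict
    models: dict
    odds: dict
    exclusions: pd.DataFrame
    modelling: pd.DataFrame

    def to_payload(self) -> dict:
        """JSON-serialisable summary of the run."""
        payload = {
            "n_modelling": int(len(self.modelling)),
            "n_excluded": int(len(self.exclusions)),
            "descriptives": self.descriptives,
            "transitions": {},
            "models": {},
            "comparisons": {},
            "interactions": {},
            "odds_ratios": {
                k: {"or": v.odds_ratio, "ci_low": v.ci_low, "ci_high": v.ci_high}
                for k, v in self.odds.items()
            },
        }
        for scheme, block in self.transitions.items():
            payload["transitions"][scheme] = {
                "counts": block["table"].counts.tolist(),
                "labels": list(block["table"].row_labels),
                "chi2": block["chi2"],
                "df": block["df"],
            }
        for name, fit in self.models["fits"].items():
            payload["models"][name] = _fit_payload(fit)
        for name, fit in self.models["interactions"].items():
            payload["interactions"][name] = (
                _fit_payload(fit) if isinstance(fit, ModelFit) else {"error": fit}
            )
        for outcome, comp in self.models["comparisons"].items():
            payload["comparisons"][outcome] = {
                "delta_aic": comp.delta_aic,
                "delta_bic": comp.delta_bic,
                "verdict": comp.verdict,
            }
        return payload


def _fit_payload(fit: ModelFit) -> dict:
    return {
        "label": fit.label,
        "n": fit.n_obs,
        "k": fit.k_params,
        "llf": fit.llf,
        "aic": fit.aic,
        "bic": fit.bic,
        "dispersion": fit.dispersion,
        "percent_correct": fit.percent_correct,
        "params": {c: fit.params[c].to_dict() for c in fit.params.columns},
        "se": {c: fit.se[c].to_dict() for c in fit.se.columns},
    }


def run_analysis(
    cohort: pd.DataFrame,
    reference: GrowthReference | None = None,
    norms: AdultStatureNorms | None = None,
    kr_tables: dict | None = None,
    config: RunConfig | None = None,
) -> AnalysisResults:
    """Classify, score and model a cohort table in memory."""
    config = config or RunConfig()
    classified, excluded = classify_cohort(
        cohort,
        reference,
        norms,
        kr_tables,
        cutoffs=config.cutoffs,
        timing_threshold=config.timing_threshold,
        month_binning=config.month_binning,
    )
    modelling, underweight = exclude_underweight(classified)
    if len(underweight):
        underweight = underweight.reindex(columns=list(cohort.columns))
        underweight["reason"] = "underweight at visit 1 (chronological)"
    exclusions = pd.concat([excluded, underweight], ignore_index=True) if len(underweight) else excluded

    panel = modelling[["glucose", "hdl", "ldl", "sbp1", "sbp2", "dbp1", "dbp2"]]
    group = modelling["sex"] if config.sex_stratified_z else None
    scores = cm.cmr_score(panel, group=group)
    modelling = pd.concat([modelling, scores[["map", "cmr", "risk_class"]]], axis=1)
    modelling["cmr_class"] = modelling["risk_class"]

    models = fit_outcome_models(modelling)
    odds = {
        "early_overweight_or_obese_chron_v1": maturity_odds(modelling, category_column="category_chron_v1"),
        "early_obese_chron_v1": maturity_odds(
            modelling, category_column="category_chron_v1", positive_categories=("obese",)
        ),
        "early_overweight_or_obese_bio_v1": maturity_odds(modelling, category_column="category_bio_v1"),
    }
    return AnalysisResults(
        descriptives=descriptives(classified),
        transitions=transition_analysis(modelling),
        models=models,
        odds=odds,
        exclusions=exclusions,
        modelling=modelling,
    )


def render_report(results: AnalysisResults) -> str:
    """Human-readable report with Table-3-style transition layout."""
    lines: list[str] = []
    d = results.descriptives
    lines.append(f"Modelling sample: {len(results.modelling)} children "
                 f"({len(results.exclusions)} excluded)")
    for s in ("male", "female"):
        b = d[s]
        lines.append(
            f"  {s}: n={b['n']}, age {b['age_v1_mean']:.2f} ({b['age_v1_sd']:.2f}), "
            f"BMI {b['bmi_v1_mean']:.2f} ({b['bmi_v1_sd']:.2f}), "
            f"%adult height {b['percent_adult_height_mean']:.1f}, "
            f"timing {b['timing']}"
        )
    for scheme, block in results.transitions.items():
        table: TransitionTable = block["table"]
        pct = block["row_percent"]
        lines.append("")
        lines.append(f"Transition (visit 1 -> visit 2), {scheme} matching "
                     f"[chi2 = {block['chi2']:.1f}, df = {block['df']}]")
        header = "".ljust(14) + "".join(lbl.rjust(18) for lbl in table.col_labels)
        lines.append(header)
        for i, row_lbl in enumerate(table.row_labels):
            cells = []
            for j in range(len(table.col_labels)):
                mark = "*" if i == j else " "  # diagonal = stable classification
                cells.append(f"{table.counts[i, j]:6d} ({pct[i, j]:3.0f}%){mark}".rjust(18))
            lines.append(row_lbl.ljust(14) + "".join(cells))
    lines.append("")
    for outcome, comp in results.models["comparisons"].items():
        lines.append(
            f"{outcome}: dBIC (biological - chronological) = {comp.delta_bic:.2f} -> {comp.verdict}"
        )
    for name, fit in results.models["fits"].items():
        lines.append(
            f"  {name}: n={fit.n_obs} AIC={fit.aic:.1f} BIC={fit.bic:.1f} "
            f"phi={fit.dispersion:.2f} correct={fit.percent_correct:.0f}%"
        )
    for key, o in results.odds.items():
        lines.append(f"  OR[{key}] = {o.odds_ratio:.2f} ({o.ci_low:.2f}-{o.ci_high:.2f})")
    return "\n".join(lines)


def run_pipeline(config: RunConfig, cohort: pd.DataFrame | None = None) -> AnalysisResults:
    """File-level run: load inputs, analyse, write the report bundle.

    Outputs in ``config.output_dir``: ``classified.csv``,
    ``exclusions.csv``, ``results.json`` (machine readable, includes a
    config echo), and ``report.txt``.  Nothing is written if any stage
    fails.
    """
    if cohort is None:
        if not config.cohort_path:
            raise ValueError("run_pipeline needs a cohort table or cohort_path")
        cohort = pd.read_csv(config.cohort_path)
    reference, norms, kr = _load_references(config)
    results = run_analysis(cohort, reference, norms, kr, config)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.modelling.to_csv(out / "classified.csv", index=False)
    results.exclusions.to_csv(out / "exclusions.csv", index=False)
    payload = results.to_payload()
    payload["config"] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()}
    with open(out / "results.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    (out / "report.txt").write_text(render_report(results) + "\n")
    logger.info("pipeline outputs written to %s", out)
    return results
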