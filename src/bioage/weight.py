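"""BMI computation, percentile matching and weight-status categories.

A child's BMI is placed on the growth reference twice: once against
peers of the same chronological age (the standard approach) and once
against peers of the same *biological* age, i.e. the reference group
that has attained the same percent of adult stature.  For an early
maturer the biological matching age is older, the reference median BMI
there is higher, and the adjusted percentile is therefore lower.

Categories follow population-surveillance cut-offs on the percentile
scale: <2nd underweight, [2, 85) healthy, [85, 95) overweight,
>=95th obese (closed lower bounds, open upper bounds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .reference import LMSReferenceTable

__all__ = [
    "WeightCategory",
    "DEFAULT_CUTOFFS",
    "WeightClassification",
    "compute_bmi",
    "bmi_percentile",
    "categorize",
    "classify_weight",
    "exclude_underweight",
]

logger = logging.getLogger(__name__)

#: (underweight/healthy, healthy/overweight, overweight/obese) percentile bounds
DEFAULT_CUTOFFS = (2.0, 85.0, 95.0)


class WeightCategory(str, Enum):
    underweight = "underweight"
    healthy = "healthy"
    overweight = "overweight"
    obese = "obese"


CATEGORY_ORDER = [
    WeightCategory.underweight.value,
    WeightCategory.healthy.value,
    WeightCategory.overweight.value,
    WeightCategory.obese.value,
]

#: ordinal score used when BMI category enters a regression (healthy = 0)
ORDINAL_SCORE = {
    WeightCategory.healthy.value: 0,
    WeightCategory.overweight.value: 1,
    WeightCategory.obese.value: 2,
}


@dataclass(frozen=True)
class WeightClassification:
    """One child's weight status under both matching schemes."""

    bmi: float
    percentile_chronological: float
    percentile_biological: float
    category_chronological: WeightCategory
    category_biological: WeightCategory


def compute_bmi(weight_kg, height_cm):
    """BMI in kg/m^2 from weight (kg) and height (cm)."""
    weight = np.asarray(weight_kg, dtype=float)
    height = np.asarray(height_cm, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise ValueError("weight and height must be positive")
    bmi = weight / (height / 100.0) ** 2
    return float(bmi) if np.ndim(bmi) == 0 else bmi


def bmi_percentile(
    bmi,
    matching_age,
    bmi_reference: LMSReferenceTable,
    month_binning: bool = False,
):
    """Percentile of ``bmi`` against the reference at ``matching_age``.

    ``matching_age`` is the chronological age for the standard scheme or
    the biological age for the maturity-adjusted scheme.  With
    ``month_binning`` the age is snapped to the nearest whole month
    before an exact-grid lookup, mirroring references tabulated by month.
    """
    age = np.asarray(matching_age, dtype=float)
    if month_binning:
        age = np.round(age * 12.0) / 12.0
    return bmi_reference.percentile(bmi, age)


def categorize(percentile, cutoffs=DEFAULT_CUTOFFS):
    """Weight category from a BMI percentile.

    Cut-offs are closed below and open above: e.g. the 85.0th percentile
    is overweight and 95.0 is obese.
    """
    under, over, obese = cutoffs
    if not (0 < under < over < obese < 100):
        raise ValueError("cut-offs must be strictly increasing within (0, 100)")
    p = np.asarray(percentile, dtype=float)
    if np.any((p <= 0) | (p >= 100)):
        raise ValueError("percentile must lie strictly inside (0, 100)")
    cats = np.select(
        [p < under, p < over, p < obese],
        [WeightCategory.underweight.value, WeightCategory.healthy.value, WeightCategory.overweight.value],
        default=WeightCategory.obese.value,
    )
    if np.ndim(percentile) == 0:
        return WeightCategory(cats.item())
    return cats


def classify_weight(
    weight_kg,
    height_cm,
    chronological_age,
    biological_age,
    bmi_reference: LMSReferenceTable,
    cutoffs=DEFAULT_CUTOFFS,
    month_binning: bool = False,
) -> WeightClassification:
    """Classify one child under chronological and biological matching."""
    bmi = compute_bmi(weight_kg, height_cm)
    p_chron = bmi_percentile(bmi, chronological_age, bmi_reference, month_binning)
    p_bio = bmi_percentile(bmi, biological_age, bmi_reference, month_binning)
    return WeightClassification(
        bmi=float(bmi),
        percentile_chronological=float(p_chron),
        percentile_biological=float(p_bio),
        category_chronological=categorize(p_chron, cutoffs),
        category_biological=categorize(p_bio, cutoffs),
    )


def exclude_underweight(
    cohort: pd.DataFrame, category_column: str = "category_chron_v1"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a classified cohort into the modelling set and underweight rows.

    Exclusion is screened on the chronological classification at the
    first visit; children who fall to underweight only under the
    biological adjustment stay in the modelling set (they remain
    described in the Table-1-style counts).
    """
    if category_column not in cohort.columns:
        raise ValueError(f"cohort lacks category column {category_column!r}")
    mask = cohort[category_column] == WeightCategory.underweight.value
    excluded = cohort[mask].copy()
    kept = cohort[~mask].copy()
    if kept.empty:
        logger.warning("every child is underweight: modelling set is empty")
    return kept, excluded
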