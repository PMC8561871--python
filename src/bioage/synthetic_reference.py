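"""Synthetic growth-reference and adult-height-prediction tables.

The British 1990 growth reference and the published adult-height
prediction coefficients are licensed datasets and are not
redistributed here.  This module instead constructs SYNTHETIC stand-ins
with the same structure and realistic magnitudes, built once at import
time from smooth curves through anchor values typical of UK children:

* height-for-age and BMI-for-age LMS tables per sex, ages 6-20;
* the girls' curve attains 91.5% of mean adult stature (163.7 cm)
  exactly at age 12, and both sexes reach their adult mean at 18, so
  the percent-of-adult-height curve is well anchored;
* a matching coefficient table for adult-height prediction whose
  intercepts are solved so that a reference-median child with
  mid-parent height at the adult mean is predicted exactly to the
  adult mean.

Real references can be supplied as CSV files instead (see
``GrowthReference.from_csv`` / ``KRCoefficientTable.from_csv``); every
pipeline entry point accepts them.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator

from .maturation import KRCoefficientTable
from .reference import (
    AdultStatureNorms,
    GrowthReference,
    LMSReferenceTable,
    Measurement,
    Sex,
)

__all__ = [
    "AGE_GRID",
    "synthetic_adult_norms",
    "synthetic_growth_reference",
    "synthetic_kr_table",
]

#: half-year age grid spanned by every synthetic table
AGE_GRID = np.arange(6.0, 20.0 + 1e-9, 0.5)

_ANCHOR_AGES = np.arange(6, 21, dtype=float)

# percent of mean adult stature attained at each integer age
_PERCENT_ANCHORS = {
    Sex.female: np.array(
        [70.2, 73.9, 77.5, 81.0, 84.5, 88.2, 91.5, 95.0, 97.6, 99.0, 99.6, 99.9, 100.0, 100.0, 100.0]
    ),
    Sex.male: np.array(
        [65.3, 69.0, 72.3, 75.5, 78.4, 81.4, 84.1, 87.4, 91.6, 96.1, 98.3, 99.4, 100.0, 100.0, 100.0]
    ),
}

# median BMI (kg/m^2) at each integer age
_BMI_M_ANCHORS = {
    Sex.female: np.array(
        [15.5, 15.7, 16.0, 16.4, 16.9, 17.5, 18.2, 18.9, 19.6, 20.2, 20.7, 21.0, 21.3, 21.6, 21.8]
    ),
    Sex.male: np.array(
        [15.5, 15.6, 15.9, 16.2, 16.6, 17.1, 17.6, 18.2, 18.9, 19.6, 20.2, 20.8, 21.3, 21.7, 22.0]
    ),
}

_BMI_L = {Sex.female: -1.4, Sex.male: -1.3}
_PUBERTAL_PEAK_AGE = {Sex.female: 12.0, Sex.male: 14.0}


def synthetic_adult_norms() -> AdultStatureNorms:
    """Mean adult statures (cm): 177.6 male, 163.7 female."""
    return AdultStatureNorms()


def _smooth(anchors: np.ndarray) -> np.ndarray:
    return PchipInterpolator(_ANCHOR_AGES, anchors)(AGE_GRID)


def _height_table(sex: Sex, norms: AdultStatureNorms) -> LMSReferenceTable:
    M = _smooth(_PERCENT_ANCHORS[sex]) / 100.0 * norms.mean(sex)
    # stature CV peaks mid-puberty when between-child maturity spread is widest
    S = 0.040 + 0.008 * np.exp(-((AGE_GRID - _PUBERTAL_PEAK_AGE[sex]) ** 2) / 4.0)
    L = np.ones_like(AGE_GRID)
    return LMSReferenceTable(Measurement.height, sex, AGE_GRID.copy(), L, M, S)


def _bmi_table(sex: Sex) -> LMSReferenceTable:
    M = _smooth(_BMI_M_ANCHORS[sex])
    base = 0.105 if sex is Sex.female else 0.100
    S = base + 0.0025 * (AGE_GRID - 6.0)
    L = np.full_like(AGE_GRID, _BMI_L[sex])
    return LMSReferenceTable(Measurement.bmi, sex, AGE_GRID.copy(), L, M, S)


def synthetic_growth_reference(norms: AdultStatureNorms | None = None) -> GrowthReference:
    """Four synthetic LMS tables (height/BMI x male/female), ages 6-20."""
    norms = norms or synthetic_adult_norms()
    tables = []
    for sex in (Sex.male, Sex.female):
        tables.append(_height_table(sex, norms))
        tables.append(_bmi_table(sex))
    return GrowthReference(tables)


def synthetic_kr_table(
    sex,
    reference: GrowthReference | None = None,
    norms: AdultStatureNorms | None = None,
) -> KRCoefficientTable:
    """Synthetic adult-height prediction coefficients for one sex.

    Stature weight rises with age (an older child's attained height
    pins down their adult height more tightly), the weight term is a
    small negative correction, and the mid-parent term is constant.
    Intercepts are solved per age so that a reference-median child with
    mid-parent height equal to the adult mean is predicted exactly to
    the adult mean stature.
    """
    sex = Sex(sex)
    norms = norms or synthetic_adult_norms()
    reference = reference or synthetic_growth_reference(norms)
    adult = norms.mean(sex)
    height = reference.height(sex)
    bmi = reference.bmi(sex)
    ages = AGE_GRID.copy()
    b_stature = np.minimum(0.45 + 0.04 * (ages - 6.0), 0.95)
    b_weight = np.full_like(ages, -0.02)
    b_midparent = np.full_like(ages, 0.30)
    median_height = np.interp(ages, height.ages, height.M)
    median_weight = np.interp(ages, bmi.ages, bmi.M) * (median_height / 100.0) ** 2
    intercept = adult - b_stature * median_height - b_weight * median_weight - b_midparent * adult
    return KRCoefficientTable(sex, ages, intercept, b_stature, b_weight, b_midparent)
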