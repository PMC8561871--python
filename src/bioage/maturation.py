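"""Somatic maturity estimation from attained stature.

The Khamis-Roche approach predicts a child's adult stature from a linear
combination of current stature, weight and mid-parent stature, with
age- and sex-specific coefficients.  The ratio of current to predicted
adult stature (percent of adult height attained) is a non-invasive
index of biological maturity: a child who has attained the percentage
that the reference population averages at age 12 is assigned biological
age 12, whatever their chronological age.  Maturity timing is then
classified from the offset (biological minus chronological age) with
the conventional +/- 1 year rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .reference import (
    AgeOutOfRangeError,
    PercentAdultHeightReference,
    Sex,
    _interp_with_bounds,
)

__all__ = [
    "Timing",
    "KRCoefficientTable",
    "MaturityAssessment",
    "midparent_height",
    "predict_adult_height",
    "percent_adult_height",
    "biological_age",
    "classify_timing",
    "assess_maturity",
]

logger = logging.getLogger(__name__)

#: offset at or beyond which a child counts as early (+) or late (-), years
TIMING_THRESHOLD_YEARS = 1.0


class Timing(str, Enum):
    early = "early"
    on_time = "on_time"
    late = "late"


@dataclass(frozen=True)
class KRCoefficientTable:
    """Age grid of adult-height prediction coefficients for one sex.

    Each row gives ``intercept + b_stature*H + b_weight*W +
    b_midparent*MP`` (cm); coefficients are linearly interpolated to the
    query age, with no extrapolation outside the grid.
    """

    sex: Sex
    ages: np.ndarray
    intercept: np.ndarray
    beta_stature: np.ndarray
    beta_weight: np.ndarray
    beta_midparent: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sex", Sex(self.sex))
        for name in ("ages", "intercept", "beta_stature", "beta_weight", "beta_midparent"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.ages.size < 2:
            raise ValueError("coefficient table needs at least 2 rows")
        if not np.all(np.diff(self.ages) > 0):
            raise ValueError("coefficient ages must be strictly increasing")

    @property
    def age_span(self) -> tuple[float, float]:
        return float(self.ages[0]), float(self.ages[-1])

    def interpolate(self, age):
        """(intercept, b_stature, b_weight, b_midparent) at ``age``."""
        age = _interp_with_bounds(age, self.ages)
        cols = tuple(
            np.interp(age, self.ages, getattr(self, name))
            for name in ("intercept", "beta_stature", "beta_weight", "beta_midparent")
        )
        if np.ndim(age) == 0:
            return tuple(float(c) for c in cols)
        return cols

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sex": self.sex.value,
                "age_years": self.ages,
                "intercept": self.intercept,
                "beta_stature": self.beta_stature,
                "beta_weight": self.beta_weight,
                "beta_midparent": self.beta_midparent,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sex) -> "KRCoefficientTable":
        required = {"sex", "age_years", "intercept", "beta_stature", "beta_weight", "beta_midparent"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"coefficient table missing columns: {sorted(missing)}")
        sub = df[df["sex"] == Sex(sex).value].sort_values("age_years")
        if sub.empty:
            raise ValueError(f"no coefficient rows for sex={Sex(sex).value}")
        return cls(
            Sex(sex),
            sub["age_years"].to_numpy(),
            sub["intercept"].to_numpy(),
            sub["beta_stature"].to_numpy(),
            sub["beta_weight"].to_numpy(),
            sub["beta_midparent"].to_numpy(),
        )

    @classmethod
    def from_csv(cls, path, sex) -> "KRCoefficientTable":
        return cls.from_frame(pd.read_csv(path), sex)


@dataclass(frozen=True)
class MaturityAssessment:
    """One child's maturity summary at a single visit."""

    predicted_adult_height: float  # cm
    percent_adult_height: float  # %
    biological_age: float  # years
    maturity_offset: float  # biological - chronological, years
    timing: Timing


def midparent_height(mother_height_cm: float, father_height_cm: float) -> float:
    """Arithmetic mean of the biological parents' statures (cm)."""
    if mother_height_cm <= 0 or father_height_cm <= 0:
        raise ValueError("parental heights must be positive")
    return 0.5 * (mother_height_cm + father_height_cm)


def predict_adult_height(age, stature_cm, weight_kg, midparent_cm, coeffs: KRCoefficientTable):
    """Predicted adult stature (cm) from the coefficient table at ``age``.

    A prediction below current stature is not an error (the linear model
    can produce it for extreme inputs) but is logged as a warning.
    """
    stature = np.asarray(stature_cm, dtype=float)
    weight = np.asarray(weight_kg, dtype=float)
    midparent = np.asarray(midparent_cm, dtype=float)
    if np.any(stature <= 0) or np.any(weight <= 0) or np.any(midparent <= 0):
        raise ValueError("stature, weight and mid-parent height must be positive")
    i, bs, bw, bm = coeffs.interpolate(age)
    pred = i + bs * stature + bw * weight + bm * midparent
    if np.any(pred < stature):
        logger.warning(
            "predicted adult height below current stature for %d input(s)",
            int(np.sum(np.atleast_1d(pred < stature))),
        )
    return float(pred) if np.ndim(pred) == 0 else pred


def percent_adult_height(current_stature_cm, predicted_adult_cm):
    """Percent of predicted adult stature attained; capped at 100 with a warning."""
    current = np.asarray(current_stature_cm, dtype=float)
    predicted = np.asarray(predicted_adult_cm, dtype=float)
    if np.any(predicted <= 0) or np.any(current <= 0):
        raise ValueError("statures must be positive")
    pct = 100.0 * current / predicted
    over = pct > 100.0
    if np.any(over):
        logger.warning("percent of adult height exceeded 100 for %d input(s); capped", int(np.sum(np.atleast_1d(over))))
        pct = np.where(over, 100.0, pct)
    return float(pct) if np.ndim(pct) == 0 else pct


def biological_age(percent, reference: PercentAdultHeightReference):
    """Age at which the reference mean percent of adult height equals ``percent``."""
    return reference.age_at_percent(percent)


def classify_timing(chronological_age, biological, threshold: float = TIMING_THRESHOLD_YEARS):
    """Timing class and offset from chronological and biological age.

    Offsets at or beyond ``+threshold`` are early, at or beyond
    ``-threshold`` late, otherwise on time ("1 year or more" rule).
    """
    chron = np.asarray(chronological_age, dtype=float)
    bio = np.asarray(biological, dtype=float)
    if np.any(chron <= 0) or np.any(bio <= 0):
        raise ValueError("ages must be positive")
    offset = bio - chron
    if np.ndim(offset) == 0:
        if offset >= threshold:
            return Timing.early, float(offset)
        if offset <= -threshold:
            return Timing.late, float(offset)
        return Timing.on_time, float(offset)
    timing = np.where(
        offset >= threshold, Timing.early.value,
        np.where(offset <= -threshold, Timing.late.value, Timing.on_time.value),
    )
    return timing, offset


def assess_maturity(
    chronological_age: float,
    stature_cm: float,
    weight_kg: float,
    mother_height_cm: float,
    father_height_cm: float,
    coeffs: KRCoefficientTable,
    reference: PercentAdultHeightReference,
    threshold: float = TIMING_THRESHOLD_YEARS,
) -> MaturityAssessment:
    """Full per-child maturity assessment at one visit."""
    mp = midparent_height(mother_height_cm, father_height_cm)
    predicted = predict_adult_height(chronological_age, stature_cm, weight_kg, mp, coeffs)
    pct = percent_adult_height(stature_cm, predicted)
    bio = biological_age(pct, reference)
    timing, offset = classify_timing(chronological_age, bio, threshold)
    return MaturityAssessment(
        predicted_adult_height=float(predicted),
        percent_adult_height=float(pct),
        biological_age=float(bio),
        maturity_offset=float(offset),
        timing=timing,
    )
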