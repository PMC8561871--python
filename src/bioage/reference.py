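"""Growth-reference tables and LMS percentile computation.

A growth reference summarises the distribution of a body measurement
(height or BMI) at each age and sex by three parameters: the Box-Cox
power ``L`` (skewness), the median ``M`` and the coefficient of
variation ``S``.  A measured value ``x`` maps to a z-score via

    z = ((x / M)**L - 1) / (L * S)        for |L| above a small threshold
    z = ln(x / M) / S                     in the limit L -> 0

and percentiles follow from the standard normal CDF.  This module also
builds the percent-of-adult-height reference curve (mean attained
stature at each age divided by mean adult stature), which is the
substrate for biological-age estimation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "Sex",
    "Measurement",
    "AgeOutOfRangeError",
    "lms_zscore",
    "lms_inverse",
    "zscore_to_percentile",
    "percentile_to_zscore",
    "LMSReferenceTable",
    "AdultStatureNorms",
    "PercentAdultHeightReference",
    "build_percent_adult_height_reference",
    "GrowthReference",
]

#: below this |L| the Box-Cox transform is replaced by its log limit
L_LOG_THRESHOLD = 1e-7


class Sex(str, Enum):
    male = "male"
    female = "female"


class Measurement(str, Enum):
    height = "height"
    bmi = "bmi"


class AgeOutOfRangeError(ValueError):
    """Query age (or percent) falls outside the reference grid: no extrapolation."""


def _as_sex(sex: "Sex | str") -> Sex:
    return Sex(sex)


def lms_zscore(value, L, M, S):
    """Z-score of ``value`` under an LMS reference point.

    Parameters may be scalars or arrays (broadcast).  Raises
    ``ValueError`` for non-positive ``value`` or ``M``.
    """
    value = np.asarray(value, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(value <= 0):
        raise ValueError("measurement value must be positive")
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("LMS parameters require M > 0 and S > 0")
    ratio = value / M
    with np.errstate(invalid="ignore", divide="ignore"):
        boxcox = (np.power(ratio, L) - 1.0) / (L * S)
        logform = np.log(ratio) / S
    z = np.where(np.abs(L) < L_LOG_THRESHOLD, logform, boxcox)
    return z.item() if z.ndim == 0 else z


def lms_inverse(z, L, M, S):
    """Measurement value at z-score ``z`` (inverse of :func:`lms_zscore`)."""
    z = np.asarray(z, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("LMS parameters require M > 0 and S > 0")
    body = 1.0 + L * S * z
    if np.any((np.abs(L) >= L_LOG_THRESHOLD) & (body <= 0)):
        raise ValueError("z lies outside the support of the LMS distribution (1 + L*S*z <= 0)")
    safe_L = np.where(np.abs(L) < L_LOG_THRESHOLD, 1.0, L)
    with np.errstate(invalid="ignore"):
        boxcox = M * np.power(1.0 + L * S * z, 1.0 / safe_L)
        logform = M * np.exp(S * z)
    value = np.where(np.abs(L) < L_LOG_THRESHOLD, logform, boxcox)
    return value.item() if value.ndim == 0 else value


def zscore_to_percentile(z):
    """Percentile (0, 100) of a standard-normal z-score."""
    z = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(z)):
        raise ValueError("z must be finite")
    p = 100.0 * norm.cdf(z)
    return p.item() if p.ndim == 0 else p


def percentile_to_zscore(percentile):
    """Inverse of :func:`zscore_to_percentile`."""
    p = np.asarray(percentile, dtype=float)
    if np.any((p <= 0) | (p >= 100)):
        raise ValueError("percentile must lie strictly inside (0, 100)")
    z = norm.ppf(p / 100.0)
    return z.item() if z.ndim == 0 else z


def _interp_with_bounds(age, grid, what="age"):
    age = np.asarray(age, dtype=float)
    out = (age < grid[0] - 1e-12) | (age > grid[-1] + 1e-12)
    if np.any(out):
        bad = np.atleast_1d(age)[np.atleast_1d(out)][0]
        raise AgeOutOfRangeError(
            f"{what} {bad:.6g} outside reference span [{grid[0]:.6g}, {grid[-1]:.6g}]"
        )
    return age


@dataclass(frozen=True)
class LMSReferenceTable:
    """Per-sex (age, L, M, S) rows for one measurement.

    Ages must be strictly increasing; M and S positive; at least two rows.
    Queries outside the age span fail with :class:`AgeOutOfRangeError`.
    """

    measurement: Measurement
    sex: Sex
    ages: np.ndarray
    L: np.ndarray
    M: np.ndarray
    S: np.ndarray

    def __post_init__(self):
        for name in ("ages", "L", "M", "S"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "measurement", Measurement(self.measurement))
        object.__setattr__(self, "sex", Sex(self.sex))
        if self.ages.size < 2:
            raise ValueError("reference table needs at least 2 rows")
        if not np.all(np.diff(self.ages) > 0):
            raise ValueError("reference ages must be strictly increasing")
        if np.any(self.M <= 0) or np.any(self.S <= 0):
            raise ValueError("reference requires M > 0 and S > 0")
        if not (self.ages.size == self.L.size == self.M.size == self.S.size):
            raise ValueError("L, M, S columns must match the age grid length")

    @property
    def age_span(self) -> tuple[float, float]:
        return float(self.ages[0]), float(self.ages[-1])

    def interpolate(self, age):
        """Linearly interpolated (L, M, S) at ``age``; no extrapolation."""
        age = _interp_with_bounds(age, self.ages)
        L = np.interp(age, self.ages, self.L)
        M = np.interp(age, self.ages, self.M)
        S = np.interp(age, self.ages, self.S)
        if np.ndim(age) == 0:
            return float(L), float(M), float(S)
        return L, M, S

    def zscore(self, value, age):
        L, M, S = self.interpolate(age)
        return lms_zscore(value, L, M, S)

    def percentile(self, value, age):
        return zscore_to_percentile(self.zscore(value, age))

    def value_at(self, z, age):
        """Measurement value at z-score ``z`` and ``age`` (inverse lookup)."""
        L, M, S = self.interpolate(age)
        return lms_inverse(z, L, M, S)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "measurement": self.measurement.value,
                "sex": self.sex.value,
                "age_years": self.ages,
                "L": self.L,
                "M": self.M,
                "S": self.S,
            }
        )


@dataclass(frozen=True)
class AdultStatureNorms:
    """Mean attained adult (18+) stature per sex, in cm."""

    mean_adult_height_male: float = 177.6
    mean_adult_height_female: float = 163.7

    def __post_init__(self):
        for v in (self.mean_adult_height_male, self.mean_adult_height_female):
            if not 140.0 < v < 220.0:
                raise ValueError("adult mean stature must lie in (140, 220) cm")

    def mean(self, sex: "Sex | str") -> float:
        sex = _as_sex(sex)
        return self.mean_adult_height_male if sex is Sex.male else self.mean_adult_height_female


@dataclass(frozen=True)
class PercentAdultHeightReference:
    """Mean percent of adult stature attained at each age, one sex.

    Percent is non-decreasing in age and ends at or below 100.  Supports
    the forward lookup (percent at age) and the monotone inverse lookup
    (age at percent) used for biological-age estimation; flat segments
    resolve to the youngest age of the segment.
    """

    sex: Sex
    ages: np.ndarray
    percents: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=float))
        object.__setattr__(self, "percents", np.asarray(self.percents, dtype=float))
        if self.ages.size < 2:
            raise ValueError("percent-adult-height reference needs at least 2 rows")
        if not np.all(np.diff(self.ages) > 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(np.diff(self.percents) < -1e-12):
            raise ValueError("percent of adult height must be non-decreasing with age")
        if np.any(self.percents <= 0) or self.percents[-1] > 100.0 + 1e-9:
            raise ValueError("percent values must lie in (0, 100]")

    @property
    def percent_span(self) -> tuple[float, float]:
        return float(self.percents[0]), float(self.percents[-1])

    def percent_at_age(self, age):
        age = _interp_with_bounds(age, self.ages)
        p = np.interp(age, self.ages, self.percents)
        return float(p) if np.ndim(age) == 0 else p

    def age_at_percent(self, percent):
        """Age at which the reference mean percent equals ``percent``.

        Monotone inverse by linear interpolation between grid rows; a
        percent lying on a flat segment maps to the youngest age of that
        segment.  Out-of-range percents raise :class:`AgeOutOfRangeError`
        reporting the clamped boundary age.
        """
        scalar = np.ndim(percent) == 0
        percent = np.atleast_1d(np.asarray(percent, dtype=float))
        lo, hi = self.percent_span
        if np.any(percent < lo - 1e-9):
            raise AgeOutOfRangeError(
                f"percent {percent.min():.4g} below reference minimum {lo:.4g} "
                f"(boundary age {self.ages[0]:.4g})"
            )
        if np.any(percent > hi + 1e-9):
            raise AgeOutOfRangeError(
                f"percent {percent.max():.4g} above reference maximum {hi:.4g} "
                f"(boundary age {self.ages[-1]:.4g})"
            )
        percent = np.clip(percent, lo, hi)
        # first grid index with percents[i] >= target -> earliest crossing
        idx = np.searchsorted(self.percents, percent, side="left")
        idx = np.clip(idx, 0, self.percents.size - 1)
        ages = np.empty_like(percent)
        for k, (p, i) in enumerate(zip(percent, idx)):
            if i == 0 or self.percents[i] == p:
                ages[k] = self.ages[i]
                continue
            p0, p1 = self.percents[i - 1], self.percents[i]
            a0, a1 = self.ages[i - 1], self.ages[i]
            ages[k] = a0 + (p - p0) / (p1 - p0) * (a1 - a0)
        return float(ages[0]) if scalar else ages

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sex": self.sex.value, "age_years": self.ages, "percent": self.percents}
        )


def build_percent_adult_height_reference(
    height_table: LMSReferenceTable, norms: AdultStatureNorms
) -> PercentAdultHeightReference:
    """Percent-of-adult-height curve: 100 * M(age) / mean adult stature."""
    if height_table.measurement is not Measurement.height:
        raise ValueError("percent-adult-height reference requires a height table")
    adult = norms.mean(height_table.sex)
    percents = 100.0 * height_table.M / adult
    return PercentAdultHeightReference(height_table.sex, height_table.ages.copy(), percents)


class GrowthReference:
    """Bundle of LMS tables keyed by (measurement, sex)."""

    def __init__(self, tables: Iterable[LMSReferenceTable]):
        self._tables: dict[tuple[Measurement, Sex], LMSReferenceTable] = {}
        for t in tables:
            self._tables[(t.measurement, t.sex)] = t

    def table(self, measurement, sex) -> LMSReferenceTable:
        key = (Measurement(measurement), Sex(sex))
        if key not in self._tables:
            raise KeyError(f"no reference table for {key[0].value}/{key[1].value}")
        return self._tables[key]

    def height(self, sex) -> LMSReferenceTable:
        return self.table(Measurement.height, sex)

    def bmi(self, sex) -> LMSReferenceTable:
        return self.table(Measurement.bmi, sex)

    def percent_adult_height(self, sex, norms: AdultStatureNorms) -> PercentAdultHeightReference:
        return build_percent_adult_height_reference(self.height(sex), norms)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([t.to_frame() for t in self._tables.values()], ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GrowthReference":
        required = {"measurement", "sex", "age_years", "L", "M", "S"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"reference table missing columns: {sorted(missing)}")
        tables = []
        for (meas, sex), grp in df.groupby(["measurement", "sex"], sort=True):
            grp = grp.sort_values("age_years")
            tables.append(
                LMSReferenceTable(
                    Measurement(meas), Sex(sex),
                    grp["age_years"].to_numpy(), grp["L"].to_numpy(),
                    grp["M"].to_numpy(), grp["S"].to_numpy(),
                )
            )
        return cls(tables)

    @classmethod
    def from_csv(cls, path) -> "GrowthReference":
        return cls.from_frame(pd.read_csv(path))
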