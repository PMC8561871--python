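"""Seeded synthetic two-visit cohorts with known maturity structure.

Real cohorts linking childhood anthropometry to late-adolescent
cardiometabolic outcomes are access-controlled, so every pipeline stage
is exercised on generated data whose latent truth is known.  Each child
carries a latent maturity offset (biological minus chronological age),
a latent adiposity z-score correlated with that offset (heavier
children tend to mature earlier), parents drawn around the adult
stature norms, and a second-visit state that tracks the first.

The generator is *pipeline-consistent*: visit-1 height is solved so
that the adult-height prediction equation reads back exactly the
latent percent of adult stature, and visit-1 BMI is placed on the
reference at the child's biological age.  With measurement noise set
to zero the classification pipeline therefore recovers the latent
biological age exactly (up to interpolation), which is what makes
latent-truth recovery checks meaningful.  The same construction gives
the directional structure of interest: under chronological matching,
early maturers' BMI percentiles are inflated and a share of them drop
a category once maturity-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .maturation import KRCoefficientTable
from .reference import AdultStatureNorms, GrowthReference, Sex
from .synthetic_reference import (
    synthetic_adult_norms,
    synthetic_growth_reference,
    synthetic_kr_table,
)

__all__ = ["GenerationError", "GeneratorConfig", "generate_cohort", "COHORT_COLUMNS"]

COHORT_COLUMNS = [
    "id", "sex", "ethnicity", "ses",
    "age_v1", "height_v1", "weight_v1",
    "age_v2", "height_v2", "weight_v2",
    "mother_height", "father_height",
    "glucose", "hdl", "ldl", "sbp1", "sbp2", "dbp1", "dbp2",
]

SES_LEVELS = ("professional", "intermediate", "junior_nonmanual", "manual_unskilled")


class GenerationError(ValueError):
    """The configuration cannot produce a coherent cohort."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a two-visit British birth-cohort subsample of
    1525 children measured at ~11.75 and ~17.7 years: per-sex
    early/on-time/late maturer shares of 32/63/5% (girls) and 8/90/2%
    (boys), biological-basis weight-category prevalences of 2/78/12/8%
    (underweight/healthy/overweight/obese), and strong tracking of
    adiposity between visits.
    """

    n_children: int = 1525
    female_fraction: float = 787 / 1525
    #: per-sex (early, on_time, late) shares; solved to a normal offset law
    timing_proportions: dict = field(
        default_factory=lambda: {"male": (0.08, 0.90, 0.02), "female": (0.32, 0.63, 0.05)}
    )
    #: optional override: offsets ~ N(0, sd) (0 -> every child exactly on time)
    maturity_offset_sd: float | None = None
    #: (underweight, healthy, overweight, obese) under biological matching
    bmi_prevalences: tuple = (0.02, 0.78, 0.12, 0.08)
    #: correlation between latent adiposity and maturity offset
    adiposity_maturity_corr: float = 0.10
    #: None -> BMI follows the reference at biological age (the chronological
    #: matching artifact emerges naturally); a number -> the reference is read
    #: at chronological age and this many kg/m^2 per year of offset are added
    #: instead (0 = no matching artifact at all, the null condition)
    bmi_inflation_per_year: float | None = None
    #: real (not artifactual) pubertal BMI elevation, kg/m^2 per year of
    #: offset at visit 1; visible under both matching schemes and transient
    #: (it does not feed the visit-2 adiposity)
    pubertal_bmi_effect_per_year: float = 0.65
    #: correlation of the latent adiposity z between visits
    tracking_correlation: float = 0.78
    # latent-risk effect sizes feeding the cardiometabolic panel
    cmr_bmi_effect: float = 0.9  # per BMI category step at visit 2
    cmr_sex_effect: float = 1.1  # male vs female
    cmr_timing_effect: float = 0.35  # early vs not early
    # measurement noise
    height_noise_sd: float = 0.25  # cm
    weight_noise_sd: float = 0.10  # kg
    # visit ages
    age_v1_mean: float = 11.75
    age_v1_sd: float = 0.20
    age_v2_mean: float = 17.71
    age_v2_sd: float = 0.36
    parent_height_sd: float = 6.5  # cm
    white_fraction: float = 0.98
    ses_probs: tuple = (0.30, 0.21, 0.25, 0.24)
    seed: int = 0

    def __post_init__(self):
        if self.n_children < 2:
            raise GenerationError("need at least 2 children")
        if not 0 <= self.female_fraction <= 1:
            raise GenerationError("female_fraction must lie in [0, 1]")
        for sex, props in self.timing_proportions.items():
            if abs(sum(props) - 1.0) > 1e-9:
                raise GenerationError(f"timing proportions for {sex} must sum to 1")
            if min(props) < 0:
                raise GenerationError("timing proportions must be non-negative")
        if abs(sum(self.bmi_prevalences) - 1.0) > 1e-9 or min(self.bmi_prevalences) < 0:
            raise GenerationError("BMI prevalences must be non-negative and sum to 1")
        for name in ("adiposity_maturity_corr", "tracking_correlation"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise GenerationError(f"{name} must lie in [-1, 1]")
        if abs(sum(self.ses_probs) - 1.0) > 1e-9:
            raise GenerationError("SES probabilities must sum to 1")


def _offset_law(props: tuple[float, float, float]) -> tuple[float, float]:
    """(mean, sd) of a normal offset with P(>= +1) and P(<= -1) as given."""
    early, _, late = props
    if early <= 0 or late <= 0 or early + late >= 1:
        raise GenerationError(
            "timing proportions need strictly positive early and late shares; "
            "use maturity_offset_sd for degenerate cases"
        )
    z_hi = norm.ppf(1.0 - early)  # (1 - mu)/sd
    z_lo = norm.ppf(late)  # (-1 - mu)/sd
    sd = 2.0 / (z_hi - z_lo)
    mu = 1.0 - sd * z_hi
    return mu, sd


def _adiposity_law(prevalences: tuple) -> tuple[float, float]:
    """(mean, sd) of the latent adiposity z hitting the category shares."""
    under, healthy, over, obese = prevalences
    if obese <= 0 or over <= 0:
        raise GenerationError("overweight and obese prevalences must be positive")
    z85 = norm.ppf(0.85)
    z95 = norm.ppf(0.95)
    a_hi = norm.ppf(1.0 - obese)  # (z95 - mu)/sd
    a_lo = norm.ppf(1.0 - obese - over)  # (z85 - mu)/sd
    sd = (z95 - z85) / (a_hi - a_lo)
    mu = z95 - sd * a_hi
    return mu, sd


def _solve_height(pi, bmi, midparent, coeffs: KRCoefficientTable, age):
    """Height at which the prediction equation reads percent ``pi`` exactly.

    Solves h = (pi/100) * (i + b_w * bmi*(h/100)^2 + b_mp * mp) / (1 - (pi/100) b_s)
    by fixed-point iteration (the weight term is a small contraction).
    """
    i, bs, bw, bm = coeffs.interpolate(age)
    f = pi / 100.0
    denom = 1.0 - f * bs
    if np.any(denom <= 0.05):
        raise GenerationError(
            "stature coefficient too close to 1/percent: prediction equation "
            "cannot be inverted for these ages/offsets"
        )
    h = f * 160.0
    for _ in range(60):
        w = bmi * (h / 100.0) ** 2
        h_new = f * (i + bw * w + bm * midparent) / denom
        if np.max(np.abs(h_new - h)) < 1e-12:
            h = h_new
            break
        h = h_new
    return h


def generate_cohort(
    config: GeneratorConfig,
    reference: GrowthReference | None = None,
    norms: AdultStatureNorms | None = None,
    kr_tables: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (cohort, latent_truth) frames, reproducible from the seed.

    The cohort frame carries only observable columns
    (:data:`COHORT_COLUMNS`); latent truths (offset, percent of adult
    height, adult height, adiposity z at both visits, true timing
    class) live in the sibling frame, keyed by ``id``.
    """
    norms = norms or synthetic_adult_norms()
    reference = reference or synthetic_growth_reference(norms)
    if kr_tables is None:
        kr_tables = {
            sex: synthetic_kr_table(sex, reference, norms) for sex in (Sex.male, Sex.female)
        }
    rng = np.random.default_rng(config.seed)
    n = config.n_children

    female = rng.random(n) < config.female_fraction
    sex = np.where(female, Sex.female.value, Sex.male.value)
    age_v1 = rng.normal(config.age_v1_mean, config.age_v1_sd, n)
    age_v2 = rng.normal(config.age_v2_mean, config.age_v2_sd, n)
    ethnicity = np.where(rng.random(n) < config.white_fraction, "white", "non_white")
    ses = rng.choice(SES_LEVELS, size=n, p=np.asarray(config.ses_probs))

    # latent maturity offsets
    offset = np.empty(n)
    offset_std = np.zeros(n)
    if config.maturity_offset_sd is not None:
        sd = config.maturity_offset_sd
        offset = rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)
        if sd > 0:
            offset_std = offset / sd
    else:
        draws = rng.standard_normal(n)
        for s in (Sex.male.value, Sex.female.value):
            mu, sd = _offset_law(config.timing_proportions[s])
            mask = sex == s
            offset[mask] = mu + sd * draws[mask]
            offset_std[mask] = draws[mask]

    # latent adiposity correlated with maturity
    mu_z, sd_z = _adiposity_law(config.bmi_prevalences)
    r = config.adiposity_maturity_corr
    eps = rng.standard_normal(n)
    zeta1 = r * offset_std + np.sqrt(max(0.0, 1.0 - r**2)) * eps
    z1 = mu_z + sd_z * zeta1

    # parents
    father = rng.normal(norms.mean(Sex.male), config.parent_height_sd, n)
    mother = rng.normal(norms.mean(Sex.female), config.parent_height_sd, n)
    midparent = 0.5 * (father + mother)

    # visit-2 latent adiposity tracks visit 1
    rho = config.tracking_correlation
    zeta2 = rho * zeta1 + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
    z2 = mu_z + sd_z * zeta2

    h1_true = np.empty(n)
    bmi1 = np.empty(n)
    pct1 = np.empty(n)
    h2_true = np.empty(n)
    bmi2 = np.empty(n)
    adult_height = np.empty(n)
    for s in (Sex.male, Sex.female):
        mask = sex == s.value
        if not np.any(mask):
            continue
        height_tab = reference.height(s)
        bmi_tab = reference.bmi(s)
        pah = reference.percent_adult_height(s, norms)
        lo, hi = height_tab.age_span
        bio_age_v1 = np.clip(age_v1[mask] + offset[mask], lo, hi)
        pct1[mask] = pah.percent_at_age(bio_age_v1)
        if config.bmi_inflation_per_year is None:
            bmi1[mask] = bmi_tab.value_at(z1[mask], bio_age_v1)
        else:
            bmi1[mask] = (
                bmi_tab.value_at(z1[mask], np.clip(age_v1[mask], lo, hi))
                + config.bmi_inflation_per_year * offset[mask]
            )
        bmi1[mask] = bmi1[mask] + config.pubertal_bmi_effect_per_year * offset[mask]
        if np.any(bmi1[mask] <= 8.0):
            raise GenerationError("generated visit-1 BMI non-physiological; check inflation/prevalences")
        h1_true[mask] = _solve_height(
            pct1[mask], bmi1[mask], midparent[mask], kr_tables[s], np.clip(age_v1[mask], lo, hi)
        )
        adult_height[mask] = 100.0 * h1_true[mask] / pct1[mask]
        bio_age_v2 = np.clip(age_v2[mask] + offset[mask], lo, hi)
        h2_true[mask] = adult_height[mask] * pah.percent_at_age(bio_age_v2) / 100.0
        bmi2[mask] = bmi_tab.value_at(z2[mask], np.clip(age_v2[mask], lo, hi))

    height_v1 = h1_true + rng.normal(0.0, config.height_noise_sd, n) if config.height_noise_sd > 0 else h1_true.copy()
    height_v2 = h2_true + rng.normal(0.0, config.height_noise_sd, n) if config.height_noise_sd > 0 else h2_true.copy()
    weight_v1 = bmi1 * (h1_true / 100.0) ** 2
    weight_v2 = bmi2 * (h2_true / 100.0) ** 2
    if config.weight_noise_sd > 0:
        weight_v1 = weight_v1 + rng.normal(0.0, config.weight_noise_sd, n)
        weight_v2 = weight_v2 + rng.normal(0.0, config.weight_noise_sd, n)

    # cardiometabolic panel at visit 2, driven by a latent risk index
    ord2 = (zeta2 * sd_z + mu_z >= norm.ppf(0.85)).astype(float) + (
        zeta2 * sd_z + mu_z >= norm.ppf(0.95)
    ).astype(float)
    early = offset >= 1.0
    risk = (
        config.cmr_bmi_effect * ord2
        + config.cmr_sex_effect * (~female).astype(float)
        + config.cmr_timing_effect * early.astype(float)
        + rng.standard_normal(n)
    )
    glucose = np.clip(5.0 + 0.10 * risk + rng.normal(0, 0.35, n), 2.5, None)
    hdl = np.clip(1.45 - 0.12 * risk + rng.normal(0, 0.22, n), 0.5, None)
    ldl = np.clip(2.15 + 0.22 * risk + rng.normal(0, 0.55, n), 0.5, None)
    sbp_true = 114.0 + 2.2 * risk + rng.normal(0, 8.0, n)
    dbp_true = np.clip(63.0 + 1.2 * risk + rng.normal(0, 6.0, n), 40.0, sbp_true - 5.0)
    sbp1 = sbp_true + rng.normal(0, 3.0, n)
    sbp2 = sbp_true + rng.normal(0, 3.0, n)
    dbp1 = dbp_true + rng.normal(0, 3.0, n)
    dbp2 = dbp_true + rng.normal(0, 3.0, n)

    ids = np.array([f"C{i:05d}" for i in range(1, n + 1)])
    cohort = pd.DataFrame(
        {
            "id": ids,
            "sex": sex,
            "ethnicity": ethnicity,
            "ses": ses,
            "age_v1": age_v1,
            "height_v1": height_v1,
            "weight_v1": weight_v1,
            "age_v2": age_v2,
            "height_v2": height_v2,
            "weight_v2": weight_v2,
            "mother_height": mother,
            "father_height": father,
            "glucose": glucose,
            "hdl": hdl,
            "ldl": ldl,
            "sbp1": sbp1,
            "sbp2": sbp2,
            "dbp1": dbp1,
            "dbp2": dbp2,
        }
    )[COHORT_COLUMNS]

    timing_true = np.where(offset >= 1.0, "early", np.where(offset <= -1.0, "late", "on_time"))
    truth = pd.DataFrame(
        {
            "id": ids,
            "true_offset": offset,
            "true_percent_adult_height": pct1,
            "true_adult_height": adult_height,
            "latent_adiposity_z_v1": z1,
            "latent_adiposity_z_v2": z2,
            "timing_true": timing_true,
        }
    )
    return cohort, truth
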