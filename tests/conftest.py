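import logging

import numpy as np
import pytest

from bioage.pipeline import run_analysis
from bioage.reference import (
    AdultStatureNorms,
    GrowthReference,
    LMSReferenceTable,
    PercentAdultHeightReference,
)
from bioage.simulate import GeneratorConfig, generate_cohort
from bioage.synthetic_reference import synthetic_adult_norms, synthetic_growth_reference

logging.getLogger("bioage").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def norms() -> AdultStatureNorms:
    return synthetic_adult_norms()


@pytest.fixture(scope="session")
def reference() -> GrowthReference:
    return synthetic_growth_reference()


@pytest.fixture(scope="session")
def pah_female(reference, norms) -> PercentAdultHeightReference:
    return reference.percent_adult_height("female", norms)


@pytest.fixture(scope="session")
def bmi_table_female(reference) -> LMSReferenceTable:
    return reference.bmi("female")


@pytest.fixture
def simple_pah() -> PercentAdultHeightReference:
    """Small girls' percent-of-adult-height grid anchored at 91.5% = age 12."""
    ages = np.array([9.0, 10.0, 11.0, 12.0, 13.0, 14.0, 18.0])
    percents = np.array([81.0, 84.5, 88.2, 91.5, 95.0, 97.6, 100.0])
    return PercentAdultHeightReference("female", ages, percents)


@pytest.fixture(scope="session")
def default_cohort():
    """Study-conditions cohort (n = 1525) with its latent truth table."""
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    cohort, _ = default_cohort
    return run_analysis(cohort)
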