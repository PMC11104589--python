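import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from petselect import (
    Cohort,
    DecisionEngine,
    PetMode,
    generate_cohort,
    make_separable_cohort,
    table1_defaults,
)
from petselect.synthetic import GroupParams

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_params():
    return table1_defaults()


@pytest.fixture(scope="session")
def default_cohort(table1_params):
    """The default synthetic study cohort (286 patients, published mix)."""
    params, missing = table1_params
    return generate_cohort(params, missing, seed=42)


@pytest.fixture(scope="session")
def reference_cohort(table1_params):
    """Synthetic reference cohort mirroring the published 770-patient mix."""
    from petselect import reference_composition

    _, missing = table1_params
    return generate_cohort(reference_composition(), missing, seed=7, id_prefix="R")


@pytest.fixture(scope="session")
def fitted_engine(reference_cohort):
    return DecisionEngine(mode=PetMode.visual_read(), seed=3).fit(reference_cohort)


@pytest.fixture(scope="session")
def default_evaluators(fitted_engine, default_cohort):
    """CV evaluators for the default cohort, shared across scenario tests."""
    return fitted_engine.evaluators(default_cohort, cv=True)


@pytest.fixture(scope="session")
def separable_cohort():
    return make_separable_cohort(n_per_group=50, gap=10.0, seed=5)


@pytest.fixture(scope="session")
def chance_cohort():
    return make_separable_cohort(n_per_group=50, gap=0.0, seed=5)


@pytest.fixture()
def toy_cohort():
    """Hand-built 4-patient cohort with one missing NPI cell."""
    df = pd.DataFrame(
        {
            "patient_id": ["a", "b", "c", "d"],
            "age": [62.0, 70.0, 66.0, 58.0],
            "sex": ["female", "male", "male", "female"],
            "apoe_e4": [0.0, 1.0, 1.0, 0.0],
            "mmse": [29.0, 21.0, 24.0, 28.0],
            "npi_total": [4.0, np.nan, 12.0, 2.0],
            "pet_visual": [0.0, 1.0, 0.0, 0.0],
            "centiloid": [5.0, 80.0, 10.0, 3.0],
            "true_label": ["CN", "AD", "FTD", "CN"],
        }
    )
    return Cohort(df)


def scaled_params(params, sizes):
    """Re-size Table-1 group parameters (helper shared by tests)."""
    return [GroupParams(**{**g.__dict__, "n": sizes[g.label]}) for g in params]
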