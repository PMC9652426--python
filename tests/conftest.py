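import numpy as np
import pytest

from healthgym.schema import CohortSchema, VariableSpec
from healthgym.simulator import default_config, simulate_cohort


@pytest.fixture(scope="session")
def toy_schema():
    """Small mixed-type schema: 3 numeric, 1 categorical, 1 binary flag."""
    variables = (
        VariableSpec("alpha", "numeric", "mg", quartiles=(1.0, 2.0, 4.0)),
        VariableSpec("beta", "numeric", "mL", quartiles=(10.0, 20.0, 40.0)),
        VariableSpec("gamma", "numeric", "", quartiles=(-1.0, 0.0, 1.0)),
        VariableSpec(
            "grade", "categorical", classes=("low", "mid", "high"),
            class_shares=(70.0, 20.0, 10.0),
        ),
        VariableSpec(
            "alpha (M)", "binary", classes=("False", "True"),
            measured_indicator_of="alpha", class_shares=(80.0, 20.0),
        ),
    )
    return CohortSchema("toy", variables, "pid", "step", 8)


@pytest.fixture(scope="session")
def toy_cohort(toy_schema):
    return simulate_cohort(default_config(toy_schema, 60, seed=11))


@pytest.fixture(scope="session")
def toy_cohort_large(toy_schema):
    return simulate_cohort(default_config(toy_schema, 400, seed=7))
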