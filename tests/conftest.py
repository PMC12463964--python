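import warnings

import numpy as np
import pytest

from ovaclock import (
    AgingCurve,
    ClassConditionalConfig,
    CohortRecord,
    MechanisticConfig,
    ModelSpec,
    fit_por_model,
    generate_class_conditional_cohort,
    generate_mechanistic_cohort,
)

# Six-record toy cohort with a finite, verified maximum-likelihood optimum
# (labels chosen so the classes overlap: no separating line exists).
TOY_AGES = [30.0, 32.0, 34.0, 38.0, 40.0, 42.0]
TOY_AMHS = [4.0, 3.0, 2.5, 1.0, 0.6, 0.3]
TOY_POR = [0, 0, 1, 1, 0, 1]


@pytest.fixture(scope="session")
def toy_cohort():
    return [
        CohortRecord(f"toy{i}", age, amh, por=bool(y))
        for i, (age, amh, y) in enumerate(zip(TOY_AGES, TOY_AMHS, TOY_POR))
    ]


@pytest.fixture(scope="session")
def cc_cohort():
    """Mid-sized class-conditional cohort shared across tests."""
    return generate_class_conditional_cohort(ClassConditionalConfig(n=4000), seed=101)


@pytest.fixture(scope="session")
def mech_cohort_truth():
    """Mechanistic cohort with its generating parameters."""
    return generate_mechanistic_cohort(MechanisticConfig(n=10000), seed=202)


@pytest.fixture(scope="session")
def mech_model(mech_cohort_truth):
    cohort, _ = mech_cohort_truth
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_por_model(cohort, ModelSpec(name="model2", center=True))


@pytest.fixture(scope="session")
def reference_curve():
    """A fixed aging curve in the realistic parameter regime."""
    return AgingCurve(k=0.25, x0=41.0, r_squared=1.0, age_domain=(25.0, 55.0), tau=0.15)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
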