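import numpy as np
import pytest
from hypothesis import settings

from woaboost.cohort import default_schema
from woaboost.synthetic import generate_exact, plant_signal, table1_spec

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def spec():
    return table1_spec()


@pytest.fixture(scope="session")
def cohort(spec):
    """Default synthetic 383-row cohort, seed 1."""
    return generate_exact(spec, seed=1)


@pytest.fixture(scope="session")
def planted_cohort(spec):
    """Cohort whose label depends only on Response and Pathology (effect 3)."""
    return generate_exact(plant_signal(spec, ["Response", "Pathology"], 3.0), seed=1)


@pytest.fixture(scope="session")
def sphere():
    center = np.array([1.0, -2.0, 3.0, 0.5, -1.5])

    def f(x):
        return float(np.sum((np.asarray(x) - center) ** 2))

    return f
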