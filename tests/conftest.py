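import numpy as np
import pytest

from indlin import (
    NOMINAL,
    SAMPLING_TIMES,
    DoseEvent,
    MichaelisMentenSystem,
    ReferenceConfig,
    reference_solve,
)

#: tight-tolerance reference configuration used as the truth oracle in
#: accuracy comparisons (the default 1e-6/1e-3 contract carries ~1e-3 of
#: its own global error and cannot certify finer agreement)
TIGHT = ReferenceConfig(atol=1e-12, rtol=1e-10)


@pytest.fixture(scope="session")
def theta():
    return NOMINAL


@pytest.fixture(scope="session")
def dose():
    return DoseEvent(3.0)


@pytest.fixture(scope="session")
def times():
    return SAMPLING_TIMES.copy()


@pytest.fixture(scope="session")
def system():
    return MichaelisMentenSystem()


@pytest.fixture(scope="session")
def tight_reference(theta, dose, times):
    """High-accuracy solution of the nonlinear system at the sampling times."""
    return reference_solve(theta, dose, times, TIGHT)
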