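import math

import pytest

import noisymh as nm


@pytest.fixture(scope="session")
def geometric():
    return nm.geometric_target()


@pytest.fixture(scope="session")
def symmetric_walk():
    return nm.integer_walk_proposal(0.5)


@pytest.fixture(scope="session")
def transient_homog():
    """Upward-biased walk + homogeneous two-point weights (transient at N=1)."""
    return nm.transient_homogeneous_config()


@pytest.fixture(scope="session")
def enumerable_weight_models():
    """The enumerable weight constructions shipped with the package."""
    eps = 2.0 - math.sqrt(3.0)
    return {
        "unit": nm.unit_weights(),
        "two_point_transient": nm.two_point_homogeneous(2.0 * eps * 3.0, eps),
        "two_point_generic": nm.two_point_homogeneous(3.0, 0.25),
        "state_dep_mod3": nm.transient_state_dependent_config(0.5)[2],
        "state_dep_growing": nm.persistent_transient_config()[2],
    }
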