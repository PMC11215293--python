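import numpy as np
import pytest

from ecoscore.ecosystem import apply_diet, build_ecosystem
from ecoscore.synthetic_models import ToySpec, generate_host_pair, generate_pair


def make_pair_ecosystem(kind, **spec_kwargs):
    """(models, diet, constrained ecosystem) for a two-member toy motif."""
    models, diet = generate_pair(ToySpec(kind=kind, **spec_kwargs))
    eco = apply_diet(build_ecosystem(models), diet)
    return models, diet, eco


@pytest.fixture(scope="session")
def competition_eco():
    return make_pair_ecosystem("competition")


@pytest.fixture(scope="session")
def neutral_eco():
    return make_pair_ecosystem("neutralism")


@pytest.fixture(scope="session")
def oneway_eco():
    return make_pair_ecosystem("crossfeed_oneway")


@pytest.fixture(scope="session")
def mutual_eco():
    return make_pair_ecosystem("crossfeed_mutual")


@pytest.fixture(scope="session")
def host_eco():
    models, diet = generate_host_pair()
    return models, diet, apply_diet(build_ecosystem(models), diet)


def assert_steady_state(eco, fluxes, tol=1e-6):
    residual = np.abs(eco.S @ fluxes)
    assert float(residual.max()) <= tol
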