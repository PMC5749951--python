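import numpy as np
import pytest

from actokin.rates import RateConstantSet, builtin_constructs
from actokin.synth import NoiseSpec, make_template_model


@pytest.fixture(scope="session")
def constructs():
    return builtin_constructs()


@pytest.fixture(scope="session")
def nm2c(constructs):
    return constructs["NM2C"]


@pytest.fixture()
def noise_1pct():
    return NoiseSpec(sd=0.01, seed=42, relative=True)


@pytest.fixture(scope="session")
def template():
    return make_template_model()


@pytest.fixture()
def binding_only_rates():
    """Reduced two-species network: M + ATP -> M.ATP only."""
    return RateConstantSet(
        construct_label="binding-only",
        k1k2_myosin=0.48,
        k_pi_basal=0.0,
    )


def rel_err(got, truth):
    return abs(got - truth) / abs(truth)
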