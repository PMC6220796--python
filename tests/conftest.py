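import numpy as np
import pytest

from divgrid import SimulationParams, run


def make_params(**kw):
    base = dict(
        area=25,
        local_limit=4,
        speciation_rate=0.2,
        colonization_rate=10.0,
        local_extinction_rate=1.0,
        duration=30.0,
        seed=42,
    )
    base.update(kw)
    return SimulationParams(**base)


@pytest.fixture(scope="session")
def equilibrium_run():
    """A fully logged run that reaches dynamic equilibrium and survives to T."""
    result = run(make_params(), engine="python")
    assert not result.extinct
    return result


@pytest.fixture(scope="session")
def fast_equilibrium_run():
    """Same conditions through the compiled kernel."""
    result = run(make_params(seed=7), engine="fast")
    assert not result.extinct
    return result


@pytest.fixture
def rng():
    return np.random.default_rng(123)
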