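import numpy as np
import pytest

from mbwater import ModelParameters, ThermoState


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def state() -> ThermoState:
    """A cold, moderately pressurised liquid state point."""
    return ThermoState(t_star=0.2, p_star=0.19)


@pytest.fixture(scope="session")
def random_states() -> list[ThermoState]:
    """A dozen reproducible state points spanning the liquid range."""
    rng = np.random.default_rng(1234)
    t = rng.uniform(0.15, 0.35, size=12)
    p = rng.uniform(0.0, 1.0, size=12)
    return [ThermoState(float(ti), float(pi)) for ti, pi in zip(t, p)]
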