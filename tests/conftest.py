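import numpy as np
import pytest

from isoturn.kinetics import CompartmentModel, Pool
from isoturn.simulate import OutputStreamSpec, gen_study


@pytest.fixture(scope="session")
def study():
    """Default 8-animal, 6-stream synthetic study (fixed seed)."""
    return gen_study(seed=7)


@pytest.fixture(scope="session")
def lactose_spec():
    """One-pool lactose-like stream truth: delay 12 h, half-life 10 h."""
    return OutputStreamSpec(
        "lactose",
        CompartmentModel(0.0, 12.0, [Pool.from_half_life(2.64, 10.0)]),
        trophic_shift=0.46,
        noise_sd=0.13,
    )


def random_same_sign_model(rng, max_pools=3):
    """Random compartment model with same-signed amplitudes and spread taus."""
    n = rng.integers(1, max_pools + 1)
    taus = np.sort(np.exp(rng.uniform(np.log(3.0), np.log(60.0), n)))
    while np.any(np.diff(taus) < 0.3):
        taus = np.sort(np.exp(rng.uniform(np.log(3.0), np.log(60.0), n)))
    sign = rng.choice([-1.0, 1.0])
    amps = sign * rng.uniform(0.2, 3.0, n)
    delay = rng.uniform(0.0, 24.0)
    c = rng.uniform(-32.0, -24.0)
    return CompartmentModel(c, delay, list(zip(amps, taus)))
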