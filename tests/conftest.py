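import numpy as np
import pytest
from dataclasses import replace

from swingtrack.simulate import SyntheticSwingSpec, generate_population, generate_swing


@pytest.fixture(scope="session")
def noiseless_spec():
    return replace(
        SyntheticSwingSpec(seed=11),
        noise=(0.0, 0.0),
        accel_bias=(0.0, 0.0, 0.0),
        gyro_bias=(0.0, 0.0, 0.0),
    )


@pytest.fixture(scope="session")
def noiseless_swing(noiseless_spec):
    return generate_swing(noiseless_spec)


@pytest.fixture(scope="session")
def planar_noiseless_swing(noiseless_spec):
    spec = replace(noiseless_spec, out_of_plane_amplitude=0.0, seed=12)
    return generate_swing(spec)


@pytest.fixture(scope="session")
def noisy_swing():
    return generate_swing(SyntheticSwingSpec(seed=21))


@pytest.fixture(scope="session")
def small_population():
    return generate_population(3, 3, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
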