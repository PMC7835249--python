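import numpy as np
import pytest

import alpc

# Shared, seeded benchmark runs; session-scoped because synthesis plus
# selection over a 60-s series is the expensive part of the suite.


@pytest.fixture(scope="session")
def ex1_report() -> alpc.ExampleReport:
    return alpc.run_example(1, snr_db=5.0, seed=1, duration_s=60.0)


@pytest.fixture(scope="session")
def ex2_report() -> alpc.ExampleReport:
    return alpc.run_example(2, snr_db=5.0, seed=1, duration_s=60.0)


@pytest.fixture(scope="session")
def ex1_noise_free() -> alpc.SimulationResult:
    return alpc.synthesize(alpc.example_recipe(1, snr_db=None, duration_s=20.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
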