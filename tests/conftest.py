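import numpy as np
import pytest

from revkernel import DDMParams, generate_gaussian_stimulus, simulate_bounded_ddm


@pytest.fixture(scope="session")
def neutral_stim():
    """Mean-zero Gaussian evidence ensemble shared by kernel tests."""
    return generate_gaussian_stimulus(20_000, 75, sigma_s=1.0, seed=11, dtype=np.float32)


@pytest.fixture(scope="session")
def bounded_sim(neutral_stim):
    """Bounded accumulation (B = 10, unit noises) on the shared ensemble."""
    params = DDMParams(bound_B=10.0, sigma_eta=1.0)
    trials, stim = simulate_bounded_ddm(params, neutral_stim, seed=12, max_duration=20.0)
    return params, trials, stim
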