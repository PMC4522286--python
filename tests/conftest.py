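import numpy as np
import pytest

from ffm import protocol as P
from ffm.synthetic import SimParams


@pytest.fixture(scope="session")
def tracking_protocol():
    return P.build_tracking_protocol()


@pytest.fixture(scope="session")
def single_tap_protocol():
    return P.build_single_tap_protocol()


@pytest.fixture(scope="session")
def multi_tap_protocol():
    return P.build_multi_tap_protocol(seed=0)


@pytest.fixture(scope="session")
def sequence_protocol():
    return P.build_sequence_protocol(P.PAPER_SEQUENCES["A"])


@pytest.fixture()
def noiseless_params():
    """Deterministic subject: no noise, no lag, instantaneous release."""
    return SimParams(
        tracking_noise_sd=0.0,
        tracking_lag=0.0,
        release_tau=1e-9,
        baseline_offset=0.0,
        tap_jitter_sd=0.0,
        tempo_drift_sd=0.0,
        tap_amplitude_cv=0.0,
        omission_prob=0.0,
        extra_tap_prob=0.0,
        max_rate=10.0,
    )
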