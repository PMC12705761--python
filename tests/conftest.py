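import numpy as np
import pytest

import percept
from percept.session import ResponseWindowConfig
from percept.synth import UnitProfile, make_profiles


@pytest.fixture(scope="session")
def windows():
    return ResponseWindowConfig()


@pytest.fixture(scope="session")
def localizer_bundle():
    """Small scrambled/non-scrambled session with strong selectivity."""
    profiles = [
        UnitProfile(
            baseline=4.0,
            latency=130.0,
            amplitudes={"nonscrambled": 60.0, "scrambled": 15.0},
            sustain=0.6,
            array=3,
        )
        for _ in range(4)
    ]
    return percept.simulate_localizer(profiles, seed=11, n_trials_per_class=40)


@pytest.fixture(scope="session")
def localizer_rates(localizer_bundle):
    net = percept.net_rate(localizer_bundle)
    arrays = localizer_bundle.units["array"].to_numpy()
    return net, percept.z_normalize(net, arrays)


@pytest.fixture(scope="session")
def fs_bundle():
    """Flash-suppression session with face-preferring sustained units."""
    profiles = [
        UnitProfile(
            baseline=5.0,
            latency=90.0,
            amplitudes={"face": 45.0, "place": 8.0},
            sustain=0.7,
            percept_gain=0.6,
            suppression_residual=0.1,
            array=2,
        )
        for _ in range(6)
    ]
    return percept.simulate_flash_suppression(
        profiles, seed=21, n_trials_per_condition=30
    )


@pytest.fixture(scope="session")
def masking_bundle():
    profiles = make_profiles(12, seed=31)
    return percept.simulate_masking(profiles, seed=32, n_trials=240)
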