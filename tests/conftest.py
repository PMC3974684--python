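import numpy as np
import pytest
from hypothesis import settings

import replilife as rl

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def exact_curve_obs() -> rl.ObservationSet:
    """Noise-free fractional counts on the curve a=1, b=10 at t=2..18."""
    t = np.arange(2.0, 20.0, 2.0)
    p = 1.0 / (1.0 + np.exp(t - 10.0))
    n = 20.0
    return rl.ObservationSet.from_arrays(t, n * p, n * (1.0 - p), condition="exact")


@pytest.fixture
def small_sim_obs() -> rl.ObservationSet:
    """6 wells x 20 animals simulated at a=0.5, b=10 (LD50 = 20), fixed seed."""
    s = rl.ReplicaSetScenario(
        true_a=0.5, true_b=10.0, n_wells=6, animals_per_well=20,
        schedule=(12.0, 16.0, 20.0, 24.0, 28.0, 32.0), seed=11,
    )
    return rl.simulate_replica_set(s)


@pytest.fixture
def default_obs() -> rl.ObservationSet:
    """One default replica-set experiment (24 wells x 25, LD50 = 18 d)."""
    return rl.simulate_replica_set(rl.ReplicaSetScenario(seed=7))
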