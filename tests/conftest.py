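import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import metapool as mp

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_studies():
    """The hand-checked toy: y = {0.1, 0.5}, v = 0.04 each."""
    return [
        mp.EffectEstimate("a", 0.1, 0.04),
        mp.EffectEstimate("b", 0.5, 0.04),
    ]


@pytest.fixture(scope="session")
def fixture_base():
    """The bundled synthetic 36-study evidence base."""
    from metapool.datasets import load_synthetic_cyp2d6

    return load_synthetic_cyp2d6()


@pytest.fixture()
def rng():
    return np.random.default_rng(20200327)


def random_effects(rng, k, v_low=0.01, v_high=0.5, mu_scale=0.6):
    """Random effect-estimate instances for oracle comparisons."""
    y = rng.normal(0.0, mu_scale, size=k)
    v = rng.uniform(v_low, v_high, size=k)
    return [
        mp.EffectEstimate(f"s{i}", float(y[i]), float(v[i])) for i in range(k)
    ]
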