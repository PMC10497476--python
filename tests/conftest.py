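import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from petkinetics.core import preset_protocol
from petkinetics.phantom import build_phantom, default_phantom_spec, feng_input

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def fine_bolus():
    """Default bolus sampled on a 0.25-s grid over 0-60 min: (t_min, cp)."""
    t = np.arange(0.0, 3600.25, 0.25) / 60.0
    return t, feng_input(t)


@pytest.fixture(scope="session")
def small_noiseless_phantom():
    """Noiseless 16x16x24 phantom on P-100f: (spec, dyn, truth, true_if)."""
    spec = default_phantom_spec((16, 16, 24), noise_alpha=0.0, seed=3)
    dyn, truth, true_if = build_phantom(spec, preset_protocol("P-100f"))
    return spec, dyn, truth, true_if


@pytest.fixture(scope="session")
def small_noisy_phantom():
    """Noisy 16x16x24 phantom on P-100f: (spec, dyn, truth, true_if)."""
    spec = default_phantom_spec((16, 16, 24), noise_alpha=0.5, seed=11)
    dyn, truth, true_if = build_phantom(spec, preset_protocol("P-100f"))
    return spec, dyn, truth, true_if
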