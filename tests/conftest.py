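import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def fish_fit_params():
    """Simulation parameters fitted to the fish experiments (N=25 group)."""
    from shoalkit.vicsek import SimParams

    return SimParams(
        n_agents=25,
        density=0.5,
        speed=0.1,
        inertia=0.63,
        noise=0.8,
        interaction_radius=1.0,
        seed=42,
    )
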