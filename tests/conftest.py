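import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def toy():
    """A 30-residue toy protein with 10 unresolved N-terminal residues."""
    from lolkit import fixtures as fx

    structure, sequence = fx.make_toy_structure(30, missing_n_terminal=10, seed=1)
    return structure, sequence


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
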