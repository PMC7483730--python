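import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """A small but full-length acquisition: 8 regions, 3 x 366 volumes."""
    from commdyn import GroundTruthSpec

    return GroundTruthSpec(n_regions=8, n_communities=2, snr=2.0, seed=101)


@pytest.fixture(scope="session")
def planted_stack():
    """Coherence stack with 3 planted communities at high snr (N=18, 1 run)."""
    from commdyn import GroundTruthSpec, generate_regional_bold, windowed_band_coherence

    spec = GroundTruthSpec(
        n_regions=18, n_communities=3, snr=3.0, n_runs=1, seed=202
    )
    ts, planted = generate_regional_bold(spec, 0, "sham")
    stack = windowed_band_coherence(ts, spec.window_length, spec.band)
    return stack, planted, spec
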