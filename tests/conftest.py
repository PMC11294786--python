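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


@pytest.fixture
def rng():
    return np.random.default_rng(20240718)


@pytest.fixture(scope="session")
def tiny_signal_cohort():
    """A small raw-signal cohort shared by extraction/pipeline tests."""
    import noctivitals as nv

    config = nv.SimulationConfig(
        n_cases=3, n_controls=3, nights_per_person=6, compliance=1.0, seed=42
    )
    roster, recordings = nv.generate_cohort(config)
    return config, roster, recordings


@pytest.fixture(scope="session")
def small_feature_cohort():
    """A feature-level cohort large enough for aggregation/diagnostics tests."""
    import noctivitals as nv

    config = nv.SimulationConfig(
        n_cases=20, n_controls=20, nights_per_person=40, seed=7
    )
    roster, nights = nv.generate_feature_cohort(config)
    return config, roster, nights
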