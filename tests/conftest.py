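import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")

from resight import Channel, CovariateTable, EncounterRecord, Event


@pytest.fixture
def small_records():
    """Five individuals over T=6 with mixed CV/HSV resights, including a
    same-day dual-channel detection for ind1 at occasion 3."""
    R = EncounterRecord
    return [
        R("ind1", 1, Channel.CV, Event.initial_capture),
        R("ind1", 3, Channel.CV, Event.resight),
        R("ind1", 3, Channel.HSV, Event.resight),
        R("ind1", 5, Channel.HSV, Event.resight),
        R("ind2", 2, Channel.CV, Event.initial_capture),
        R("ind2", 4, Channel.HSV, Event.resight),
        R("ind3", 1, Channel.CV, Event.initial_capture),
        R("ind4", 3, Channel.CV, Event.initial_capture),
        R("ind4", 6, Channel.CV, Event.resight),
        R("ind5", 6, Channel.CV, Event.initial_capture),
    ]


@pytest.fixture
def small_covariates():
    return CovariateTable(
        pd.DataFrame(
            {
                "individual_id": [f"ind{i}" for i in range(1, 6)],
                "sex": ["F", "M", "M", "F", "M"],
                "wing_length": [48.1, 49.0, 50.2, 47.5, 48.8],
                "first_occasion": [1, 2, 1, 3, 6],
            }
        )
    )


def random_history(rng: np.random.Generator, n: int, T: int):
    """A random valid capture history with its first-capture vector."""
    e = rng.integers(1, T + 1, size=n)
    Y = np.zeros((n, T), dtype=np.int8)
    Y[np.arange(n), e - 1] = 1
    later = (np.arange(1, T + 1)[None, :] > e[:, None]) & (rng.random((n, T)) < 0.4)
    Y[later] = 1
    return Y, e
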