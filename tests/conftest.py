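import numpy as np
import pandas as pd
import pytest

from elncut import default_config, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Mechanistic-mode cohort at the frozen default configuration."""
    return generate_cohort(default_config(n_patients=10_000, seed=11))


@pytest.fixture(scope="session")
def piecewise_cohort():
    """Piecewise-mode cohort with the planted breakpoint at 16 ELNs."""
    return generate_cohort(default_config(n_patients=50_000, seed=5, mode="piecewise"))


@pytest.fixture()
def toy_survival():
    """Tiny survival table with all events at months 1, 2, 3."""
    return pd.DataFrame(
        {"survival_months": [1.0, 2.0, 3.0], "death_event": [1, 1, 1]}
    )


def make_survival_frame(times, events):
    return pd.DataFrame(
        {
            "survival_months": np.asarray(times, dtype=float),
            "death_event": np.asarray(events, dtype=int),
        }
    )
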