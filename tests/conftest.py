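import numpy as np
import pandas as pd
import pytest

from bundlechoice import CohortConfig, default_delay_grid, simulate_cohort


@pytest.fixture(scope="session")
def grid():
    return default_delay_grid()


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-participant stochastic cohort shared across tests."""
    return simulate_cohort(CohortConfig(n_participants=60, seed=11))


@pytest.fixture(scope="session")
def deterministic_cohort():
    """Noise-free value maximizers: the model holds exactly."""
    cfg = CohortConfig(
        n_participants=40, seed=7,
        inverse_temperature=float("inf"), lapse_rate=0.0,
        inattentive_fraction=0.0,
    )
    return simulate_cohort(cfg)


def null_log_id_table(n_participants: int, rng: np.random.Generator) -> pd.DataFrame:
    """Long-format table with no condition or group effects (pure noise)."""
    rows = []
    for pid in range(n_participants):
        group = "ascending" if pid % 2 == 0 else "descending"
        for bs in (1, 3, 9):
            rows.append((pid, group, bs, rng.normal()))
    return pd.DataFrame(
        rows, columns=["participant_id", "order_group", "bundle_size", "log10_id"]
    )
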