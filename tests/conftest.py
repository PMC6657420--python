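import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from altexpress import (
    CohortSimConfig,
    DriverEventSpec,
    ExpressionMatrix,
    PassengerEventSpec,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """200-sample cohort with one mutation driver and one passenger."""
    cfg = CohortSimConfig(
        n_samples=200,
        n_genes=500,
        n_tfs=4,
        targets_per_tf=30,
        driver_events=[DriverEventSpec("mutation", 0.3, 1.0, 0)],
        passenger_events=[PassengerEventSpec("mutation", 0.3)],
        library_size=25_000,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def cnv_cohort():
    """Small cohort with planted amplification and deletion drivers."""
    cfg = CohortSimConfig(
        n_samples=60,
        n_genes=100,
        n_tfs=2,
        targets_per_tf=15,
        driver_events=[
            DriverEventSpec("amplification", 0.3, 0.5, 0),
            DriverEventSpec("deletion", 0.2, 0.5, 1),
        ],
        library_size=5_000,
        seed=3,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def count_matrix():
    rng = np.random.default_rng(7)
    df = pd.DataFrame(
        rng.poisson(50, size=(40, 12)),
        index=[f"g{i:02d}" for i in range(40)],
        columns=[f"s{j:02d}" for j in range(12)],
    )
    return ExpressionMatrix(df, "counts")
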