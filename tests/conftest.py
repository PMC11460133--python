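import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from schoolpa.config import PopulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_population():
    """The default synthetic survey at seed 1 (full size, n = 6906)."""
    from schoolpa.population import generate_population

    cfg = PopulationConfig(seed=1)
    return generate_population(cfg)


@pytest.fixture(scope="session")
def filtered_population(default_population):
    from schoolpa.population import apply_school_filter

    participants, determinants = default_population
    return apply_school_filter(participants, determinants)


@pytest.fixture()
def small_population():
    """A fast, small synthetic survey for unit tests."""
    from schoolpa.population import generate_population

    cfg = PopulationConfig(seed=7, n_surveyed=800, n_clusters=20,
                           n_districts=4)
    return generate_population(cfg)


def make_participants(
    n: int,
    rng: np.random.Generator | None = None,
    **overrides,
) -> pd.DataFrame:
    """Hand-rolled participant frame for targeted unit tests."""
    rng = rng or np.random.default_rng(0)
    df = pd.DataFrame({
        "id": np.arange(n),
        "district": rng.choice(["D00", "D01"], size=n),
        "cluster_id": rng.choice([f"C{i}" for i in range(4)], size=n),
        "age": rng.integers(12, 18, size=n),
        "gender": rng.choice(["male", "female", "diverse"], size=n,
                             p=[0.45, 0.45, 0.1]),
        "disability": rng.uniform(size=n) < 0.1,
        "deprivation": rng.choice(["low", "mid", "high", "unknown"],
                                  size=n),
        "attends_school": np.ones(n, dtype=bool),
        "takes_pe": rng.uniform(size=n) < 0.6,
        "base_weight": np.ones(n),
        "eth_maori": rng.uniform(size=n) < 0.2,
        "eth_european": np.ones(n, dtype=bool),
    })
    for key, value in overrides.items():
        df[key] = value
    return df
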