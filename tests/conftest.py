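import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phenet.synthetic_data import (
    ComorbiditySpec,
    OrderingSpec,
    SharedPairSpec,
    SimulationConfig,
    simulate_dataset,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_config() -> SimulationConfig:
    """Small study with planted genetic links, comorbidity and ordering."""
    return SimulationConfig(
        n_diseases=8,
        n_patients=3000,
        n_snps=100,
        seed=11,
        baseline_prevalence=0.12,
        planted_shared_pairs=[
            SharedPairSpec("101", "102", 2),
            SharedPairSpec("103", "104", 1, via_block=True),
            SharedPairSpec("105", "106", 1),
        ],
        planted_comorbidity=[
            ComorbiditySpec("101", "102", 3.0),
            ComorbiditySpec("103", "104", 3.0),
        ],
        planted_orderings=[OrderingSpec("101", "102", 0.9, 2.0)],
    )


@pytest.fixture(scope="session")
def planted_data(planted_config):
    return simulate_dataset(planted_config)


@pytest.fixture()
def tiny_events() -> pd.DataFrame:
    """Four patients with hand-written diagnosis histories."""
    rows = [
        ("p1", "A", "2000-01-01"),
        ("p1", "B", "2001-01-01"),
        ("p1", "C", "2002-01-01"),
        ("p1", "D", "2003-01-01"),
        ("p2", "A", "2000-06-01"),
        ("p2", "B", "2005-06-01"),
        ("p3", "B", "2000-01-01"),
        ("p3", "A", "2001-01-01"),
        ("p4", "C", "2004-01-01"),
    ]
    df = pd.DataFrame(rows, columns=["patient_id", "phenocode", "date"])
    df["date"] = pd.to_datetime(df["date"])
    return df


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
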