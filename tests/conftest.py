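import numpy as np
import pandas as pd
import pytest

from gradasym import synthetic as syn
from gradasym.config import PipelineConfig
from gradasym.io_core import CohortTable, ParcellationScheme, canonical_parcellation_table


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def scheme() -> ParcellationScheme:
    """Full-size 360-parcel scheme with 12 networks."""
    return syn.make_parcellation(180, 12, seed=1)


@pytest.fixture(scope="session")
def small_scheme() -> ParcellationScheme:
    """8 parcels (4 pairs), 2 networks, for hand-checkable tests."""
    nets = np.array(["Vis1", "Vis1", "SMN", "SMN"])
    return ParcellationScheme(canonical_parcellation_table(4, nets))


@pytest.fixture(scope="session")
def cohort() -> CohortTable:
    return syn.simulate_cohort(n_per_group=30, n_sites=5, seed=2)


def phenotype_frame(**overrides) -> pd.DataFrame:
    base = pd.DataFrame(
        {
            "subject_id": ["s1", "s2", "s3", "s4"],
            "group": ["autism", "NAI", "autism", "NAI"],
            "age": [10.0, 25.0, 15.0, 30.0],
            "site": ["A", "A", "B", "B"],
            "fiq": [105.0, 110.0, 95.0, 120.0],
            "mean_fd": [0.10, 0.12, 0.08, 0.15],
        }
    )
    for k, v in overrides.items():
        base[k] = v
    return base
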