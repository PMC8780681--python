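import numpy as np
import pandas as pd
import pytest

from fragend.regions import TargetRegion
from fragend.synthetic import CohortConfig, generate_cohort


@pytest.fixture
def small_panel() -> list[TargetRegion]:
    return [
        TargetRegion("R001", "chrS", 1000, 1500, 1050, 1075, "+", "COAD"),
        TargetRegion("R002", "chrS", 3000, 3500, 3425, 3450, "-", "RCC"),
    ]


@pytest.fixture
def tiny_config() -> CohortConfig:
    """A desk-size cohort: 8 regions, 12 samples, one batch."""
    return CohortConfig(
        n_regions=8,
        n_informative_regions=3,
        n_healthy=6,
        n_cancer=6,
        batch_sizes=(12,),
        molecules_per_region_mean=60.0,
        seed=11,
    )


@pytest.fixture
def tiny_cohort(tiny_config):
    records, truth, metadata = generate_cohort(tiny_config)
    return records, truth, metadata


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
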