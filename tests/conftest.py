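from pathlib import Path

import numpy as np
import pytest

from trihelix import domain_search as ds
from trihelix import synthetic_data as sd

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture(scope="session")
def seed_alignment() -> dict[str, str]:
    return sd.make_seed_alignment()


@pytest.fixture(scope="session")
def seed_profile(seed_alignment) -> ds.ProfileModel:
    return ds.build_profile(seed_alignment)


@pytest.fixture(scope="session")
def calibrated_profile(seed_profile) -> ds.ProfileModel:
    return ds.calibrate_evalue(seed_profile, decoy_count=300, rng_seed=0)


@pytest.fixture(scope="session")
def table1_path() -> Path:
    return FIXTURES / "osmsl_table1.tsv"


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
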