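import numpy as np
import pytest

from cnvband.synthdata.cohort import generate_cohort
from cnvband.synthdata.maps import generate_marker_map


@pytest.fixture(scope="session")
def small_map():
    """1 chromosome, 8 bands x 40 markers (acen in the middle)."""
    return generate_marker_map(1, 40, 8, seed=11)


@pytest.fixture(scope="session")
def two_chrom_map():
    return generate_marker_map(2, 50, 8, seed=1)


@pytest.fixture(scope="session")
def cohort_small():
    return generate_cohort(
        20,
        20,
        {"White": 0.8, "AA": 0.1, "Other": 0.1},
        {"NM": 0.5, "IA": 0.5},
        seed=3,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
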