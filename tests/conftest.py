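import pytest

from twinscope.cohort import FamilyCohort
from twinscope.config import SimulationConfig
from twinscope.panel import default_panel


@pytest.fixture(scope="session")
def cohort():
    return FamilyCohort.default()


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture
def small_cfg():
    """A light genotype panel with 10 planted co-segregating SNPs."""
    return SimulationConfig(
        seed=42,
        n_snps_panel=100,
        n_snps_background=60,
        coseg_fraction=0.10,
        invariant_rate=0.20,
        missing_rate=0.0,
    )
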