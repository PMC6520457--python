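import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pairedscreen import SimConfig, simulate_screen

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_library_frame() -> pd.DataFrame:
    """Two targeting guides on one gene, one targeting another, one control."""
    return pd.DataFrame(
        {
            "sgrna_id": ["a_sg1", "a_sg2", "b_sg1", "nt_sg01"],
            "gene_id": ["geneA", "geneA", "geneB", "non-targeting"],
            "spacer": ["ACGTACGTACGTACGTACGT", "TTTTCCCCGGGGAAAATTTT",
                       "GATCGATCGATCGATCGATC", "CCCCCCCCCCCCCCCCCCCC"],
        }
    )


@pytest.fixture(scope="session")
def small_screen():
    """A 60-gene paired screen with every archetype planted."""
    return simulate_screen(SimConfig(n_genes=60, coverage=100, seed=42))


@pytest.fixture(scope="session")
def medium_screen():
    """A 400-gene paired screen at protocol coverage."""
    return simulate_screen(SimConfig(n_genes=400, seed=7))
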