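import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from telandscape import default_taxonomy, load_default_rates
from telandscape import synthetic_data as sd


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def rates():
    return load_default_rates()


@pytest.fixture(scope="session")
def small_genome_sim():
    """A small multi-class synthetic genome shared across modules."""
    config = sd.SimulationConfig(
        seed=20_001,
        genome_length=100_000,
        consensi=[
            sd.ConsensusSpec("CR1_syn", "LINE/CR1", length=1_000),
            sd.ConsensusSpec("ERV2_syn", "LTR/ERVK", length=800),
            sd.ConsensusSpec("MIR_syn", "SINE/MIR", length=200),
            sd.ConsensusSpec("hAT_syn", "DNA/hAT", length=400),
        ],
        insertions=[
            sd.InsertionPlan("CR1_syn", 20, age_My=15.0),
            sd.InsertionPlan("ERV2_syn", 10, age_My=30.0),
            sd.InsertionPlan("MIR_syn", 15, K_percent=40.0),
            sd.InsertionPlan("hAT_syn", 5, age_My=60.0),
        ],
    )
    return sd.simulate_genome(config)


@pytest.fixture(scope="session")
def screen_fixture():
    """The standard planted screening set (all categories + boundaries)."""
    line_specs, erv_specs = sd.default_screen_plan()
    return sd.simulate_elements(line_specs, erv_specs, seed=77)
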