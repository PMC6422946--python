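import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from methanonet.containers import OtuTable
from methanonet.synthetic import (GeneratorConfig, build_design,
                                  simulate_ancillary, simulate_counts,
                                  simulate_isotopes)


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def experiment(default_config):
    """One full synthetic experiment (3 soils x 36 samples, 90 OTUs)."""
    design = build_design(default_config)
    table, truth = simulate_counts(default_config, design)
    return design, table, truth


@pytest.fixture(scope="session")
def isotope_series(default_config, experiment):
    design, _, truth = experiment
    return simulate_isotopes(default_config, design, truth)


@pytest.fixture(scope="session")
def ancillary(default_config, experiment):
    design, _, truth = experiment
    return simulate_ancillary(default_config, design, truth)


@pytest.fixture
def toy_table() -> OtuTable:
    counts = pd.DataFrame(
        {"s1": [5, 3, 0], "s2": [1, 7, 2], "s3": [4, 4, 4]},
        index=pd.Index(["OTU_A001", "OTU_B001", "OTU_B002"], name="otu_id"))
    taxonomy = pd.Series(
        ["Archaea;Euryarchaeota;Methanomicrobia",
         "Bacteria;Firmicutes;Clostridia",
         "Bacteria;Chloroflexi;Anaerolineae"],
        index=counts.index, name="taxonomy")
    return OtuTable(counts, taxonomy)
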