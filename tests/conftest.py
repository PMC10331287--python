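import pytest

from oddlipid import pipeline, synthetic_fixtures
from oddlipid.chem_core import FattyAcyl, LibraryConfig, enumerate_odd_library


@pytest.fixture(scope="session")
def small_library():
    """Compact library (two odd chains, one even partner) for fast enumeration."""
    config = LibraryConfig(
        subclasses=("FFA", "DAG", "TAG", "PA", "PC", "PI", "LPE", "SM", "Cer"),
        odd_carbons=(15, 17),
        even_carbons=(18,),
        double_bonds=(0, 1),
    )
    return enumerate_odd_library(config)


@pytest.fixture(scope="session")
def study():
    """The default simulated three-group study (shared across tests)."""
    config = synthetic_fixtures.SimulationConfig(seed=7)
    return synthetic_fixtures.simulate_study(config)


@pytest.fixture(scope="session")
def study_results(study):
    """Full pipeline run on the default study: both group comparisons."""
    return pipeline.differential_analysis(
        study.peaks,
        study.design,
        study.is_assignments,
        comparisons=[("CC-A", "CC-B"), ("CC-B", "CC-C")],
    )


@pytest.fixture
def fa():
    return FattyAcyl
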