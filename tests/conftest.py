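import pytest

from clonetrack.simulate import (
    AmpliconDesign,
    SimulationConfig,
    build_germline_set,
    default_founder_spec,
    simulate_lineage,
)
from clonetrack.vdj import VDJAligner


@pytest.fixture(scope="session")
def base_config() -> SimulationConfig:
    return SimulationConfig(n_v=3, n_d=2, n_j=2, random_seed=7)


@pytest.fixture(scope="session")
def reference(base_config):
    return build_germline_set(base_config)


@pytest.fixture(scope="session")
def founder_spec(reference):
    return default_founder_spec(reference, seed=7)


@pytest.fixture(scope="session")
def design(reference):
    return AmpliconDesign.from_reference(reference)


@pytest.fixture(scope="session")
def aligner(reference):
    return VDJAligner(reference)


@pytest.fixture(scope="session")
def small_lineage(reference, founder_spec):
    """Five engineered CDR3 groups (one unproductive), two SHM rounds."""
    return simulate_lineage(
        reference,
        founder_spec,
        n_rounds=2,
        mutation_rate=0.002,
        seed=11,
        n_groups=5,
        unproductive_groups=1,
        founder_mutation_count=10,
        fr_replacement_retention=0.5,
    )
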