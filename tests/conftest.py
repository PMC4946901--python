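import pytest

from clipcims import (
    SimConfig,
    filter_unique,
    generate_genome,
    remove_duplicates,
    simulate_clip_tags,
)


@pytest.fixture(scope="session")
def default_genome():
    """One simulated genome at the study-condition defaults."""
    return generate_genome(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_sim(default_genome):
    return simulate_clip_tags(default_genome)


@pytest.fixture(scope="session")
def filtered_tags(default_sim):
    return filter_unique(remove_duplicates(default_sim.tags))
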