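import pytest

from cladepan.metrics import compute_all_pairs
from cladepan.simulate import SimulationConfig, simulate_clade


@pytest.fixture(scope="session")
def small_clade():
    """4 species x 2 strains, ~110-kb genomes: quick end-to-end material."""
    config = SimulationConfig(
        seed=11,
        n_species=4,
        strains_per_species=2,
        root_family_count=120,
        gain_rate=80,
        loss_rate=30,
    )
    return simulate_clade(config)


@pytest.fixture(scope="session")
def study_clade():
    """The separability study: 8 species x 3 strains, 1% intra / >=5% inter
    divergence, ~200-kb genomes (222 families x ~900 nt), seed 42."""
    config = SimulationConfig(
        seed=42,
        n_species=8,
        strains_per_species=3,
        intra_species_divergence=0.01,
        root_family_count=222,
        gain_rate=50,
        loss_rate=20,
    )
    return simulate_clade(config)


@pytest.fixture(scope="session")
def study_metrics(study_clade):
    records, _ = study_clade
    return compute_all_pairs(records)
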