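import pytest

from paleocatch.synthetic import GeneratorConfig, generate_species_pool, simulate_dataset
from paleocatch.types import (
    AssemblageRecord,
    Dataset,
    PeriodCatch,
    SiteRecord,
    TaxonRecord,
    TraitRecord,
)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def pool(default_config):
    return generate_species_pool(default_config)


@pytest.fixture(scope="session")
def sim_dataset(default_config):
    dataset, truth = simulate_dataset(default_config)
    return dataset, truth


def make_taxa(*specs):
    """specs: (taxon_id, name, rank, lineage tuple, fish_class)"""
    return {s[0]: TaxonRecord(*s) for s in specs}


@pytest.fixture
def tiny_dataset():
    """One quantified site, a class record plus two species."""
    taxa = make_taxa(
        ("cl1", "Actinopterygii", "class", (), "bony"),
        ("sp1", "Genidens barbus", "species",
         ("Actinopterygii", "Siluriformes", "Ariidae", "Genidens"), "bony"),
        ("sp2", "Micropogonias furnieri", "species",
         ("Actinopterygii", "Perciformes", "Sciaenidae", "Micropogonias"), "bony"),
    )
    sites = {
        "s1": SiteRecord("s1", "Site one", -26.5, "A", mesh_mm=2.0, volume_m3=2.0,
                         median_age_cal_bp=2000.0)
    }
    assemblages = [
        AssemblageRecord("s1", "Sambaqui", {"cl1": 50, "sp1": 25, "sp2": 25})
    ]
    traits = {
        "Genidens barbus": TraitRecord("Genidens barbus", 3.5, "invertivore", 120.0, 12000.0),
        "Micropogonias furnieri": TraitRecord(
            "Micropogonias furnieri", 3.6, "invertivore", 60.0, 4600.0),
    }
    periods = {
        "P1": PeriodCatch("P1", frozenset({"Genidens barbus", "Micropogonias furnieri"}))
    }
    return Dataset(taxa=taxa, sites=sites, assemblages=assemblages, traits=traits,
                   periods=periods)
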