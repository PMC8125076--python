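"""Shared fixtures: small synthetic communities with known ground truth."""

import pytest

import motukit as mk


@pytest.fixture(scope="session")
def small_community() -> mk.Community:
    """Three species across two continents; one species confined to one lake."""
    species = [
        mk.SpeciesSpec(f"sp{i:02d}", n_core_genes=60, n_accessory_pool=60,
                       accessory_freq=0.3, genome_length=40_000, n_genomes=4,
                       within_ani=98.0)
        for i in range(1, 4)
    ]
    sites = [
        mk.SiteSpec("lakeA", "regEU", "Sweden", "Europe", n_samples=2,
                    planted_abundances={"sp01": 0.3, "sp02": 0.1}),
        mk.SiteSpec("lakeB", "regNA", "Canada", "NorthAmerica", n_samples=1,
                    planted_abundances={"sp01": 0.2, "sp03": 0.4}),
    ]
    return mk.generate_community(species, sites, seed=7, reads_per_sample=4000)


@pytest.fixture(scope="session")
def small_catalog(small_community) -> mk.MOTUCatalog:
    ani = mk.pairwise_ani(small_community.sequences)
    meta = [
        mk.GenomeRecord(
            genome_id=row["genome_id"], completeness=row["completeness"],
            contamination=row["contamination"], site=row["site"], region=row["region"],
            country=row["country"], continent=row["continent"],
        )
        for _, row in small_community.genome_metadata().iterrows()
    ]
    return mk.cluster_motus(ani, meta)


@pytest.fixture(scope="session")
def small_genome_records(small_community) -> list[mk.GenomeRecord]:
    return [
        mk.GenomeRecord(
            genome_id=row["genome_id"], completeness=row["completeness"],
            contamination=row["contamination"], site=row["site"], region=row["region"],
            country=row["country"], continent=row["continent"],
        )
        for _, row in small_community.genome_metadata().iterrows()
    ]
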