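# motukit

Species-level population genomics for genome collections recovered from
metagenomes. `motukit` is for microbial ecologists who have a pile of
metagenome-assembled genomes (MAGs), single-amplified genomes (SAGs) and
reference isolates — each with a CheckM-style completeness and
contamination estimate and a sampling location — plus metagenome read
sets, and who want to answer: *which genomes are the same species, what
is in each species' core genome given that most MAGs are incomplete,
where is each species found and how abundant is it, and which metabolic
markers does each species carry?*

## What it computes

**mOTUs.** Genomes are clustered into metagenomic operational taxonomic
units at the conventional species boundary: pairs with average
nucleotide identity (ANI) above 95% form edges, connected components
form the mOTUs. Quality is handled in two tiers — genomes with
completeness ≥ 70% and contamination ≤ 5% seed the graph; genomes at
50–70% completeness are recruited into an existing mOTU when they
share > 95% ANI with one of its seeds; everything else is kept as
"excluded" with a reason. ANI is estimated from canonical k-mer sets
(k = 21) via the MinHash transform

    J = |A∩B| / |A∪B|,   D = −(1/k)·ln(2J/(1+J)),   ANI = 100·(1−D)

or imported from a FastANI-style TSV.

**Core vs accessory genes.** For an mOTU with genomes of completeness
c_i, a gene cluster with presence profile x ∈ {0,1}^N is core when

    Σ_{x_i=1} ln c_i + Σ_{x_i=0} ln(1−c_i)  >  Σ_{x_i=1} ln p_i + Σ_{x_i=0} ln(1−p_i)

where p_i is genome i's accessory carriage probability (its observed
fraction of the mOTU's accessory gene pool). The left side explains
absences by genome incompleteness; the right side by sporadic carriage.
Since p depends on the partition, the assignment is iterated to a fixed
point (`CorePangenomeModel(...).fit()` → `GenePartitionResults`). A gene
observed in *no* member is reported "absent", never classified.

**Abundance and occupancy.** Each metagenome is subsampled to 1,000,000
reads and every read is matched at 100% identity (full-length exact
substring, either strand) against all genomes of all mOTUs
competitively: one matching mOTU counts 1, k mOTUs count 1/k each,
no match is "unmapped". Abundance = count / subsample size; per-site
occupancy is the mean over the site's samples, with presence called at
≥ 0.03% (0.0003).

**Traits and biogeography.** Marker-protein hits (PsaA, Sqr, DsrA,
SoxB, Cyc2, HyaB, HyhL, NifH, FCC, AclB, …) filtered at ≥ 80% query
coverage and ≥ 50% identity (≥ 80% for PsaA) yield a per-mOTU
core/accessory/absent trait matrix, classified with the same likelihood
rule. Combining member-genome origins with occupancy classifies each
mOTU as **cosmopolitan** (≥ 2 continents), **endemic** (one site or one
region) or **regional**.

A synthetic-community generator (`motukit.synthetic`) plants species
pangenomes, degraded genomes, divergence-controlled sequences and read
mixtures with full ground truth, so the whole chain is testable without
external data. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

Two planted species, one seeded on both continents, one only in a
Swedish lake:

```python
import motukit as mk
from motukit.pangenome import fit_motu_partitions
from motukit.biogeo import site_hierarchy_from_meta

species = [
    mk.SpeciesSpec("sp01", n_core_genes=60, n_accessory_pool=60, accessory_freq=0.3,
                   genome_length=40_000, n_genomes=4, within_ani=98.0),
    mk.SpeciesSpec("sp02", n_core_genes=60, n_accessory_pool=60, accessory_freq=0.3,
                   genome_length=40_000, n_genomes=4, within_ani=98.0),
]
sites = [
    mk.SiteSpec("lakeSE", "Scandinavia", "Sweden", "Europe", 2,
                {"sp01": 0.30, "sp02": 0.10}),
    mk.SiteSpec("lakeCA", "Ontario", "Canada", "NorthAmerica", 1,
                {"sp01": 0.20}),
]
com = mk.generate_community(species, sites, seed=7, reads_per_sample=20_000)

ani = mk.pairwise_ani(com.sequences)
records = [mk.GenomeRecord(genome_id=r["genome_id"], completeness=r["completeness"],
                           contamination=r["contamination"], site=r["site"],
                           region=r["region"], country=r["country"],
                           continent=r["continent"])
           for _, r in com.genome_metadata().iterrows()]
catalog = mk.cluster_motus(ani, records)

fits = fit_motu_partitions(com.presence_matrix(), com.completeness, catalog.motus)
print(fits["mOTU01"].summary())

matrix = mk.profile_samples(com.reads, com.sequences, catalog.motu_of(),
                            subsample=20_000, seed=7)
occupancy = mk.aggregate_by_location(matrix, com.sample_metadata())
bio = mk.classify_biogeography(catalog, records, occupancy,
                               site_hierarchy_from_meta(com.sample_metadata()))
print(bio.table[["motu_id", "classification", "continents"]])
```

Clustering recovers the two planted species exactly
(`mOTU01 = sp01_g01..g04`, `mOTU02 = sp02_g01..g04`). The pangenome
summary for mOTU01 reads:

```
Core/accessory pangenome partition
==================================
genomes:               4
gene clusters:         102
core genes:            50
accessory genes:       52
mean completeness:     0.900
mean carriage prob:    0.409
iterations:            3
converged:             True
```

50 of the 60 planted core genes are confidently core from only four
90%-complete genomes (the rest are indistinguishable from high-frequency
accessory genes at this depth — the separation sharpens with more
genomes). The abundance matrix lands on the planted fractions
(0.297/0.298 vs planted 0.30; 0.201 vs 0.20; 0.101 vs 0.10), and the
biogeography table prints:

```
  motu_id classification           continents
0  mOTU01   cosmopolitan  Europe;NorthAmerica
1  mOTU02        endemic               Europe
```

The same chain is available from the shell via the `motukit` console
script (`simulate`, `ani`, `cluster`, `coregenes`, `abundance`,
`traits`, `biogeo`; see `motukit --help`).

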