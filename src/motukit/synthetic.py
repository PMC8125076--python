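"""Synthetic multi-species communities with known ground truth.

Every downstream stage of the pipeline (ANI clustering, core/accessory
partitioning, abundance profiling, biogeography) is exercised against
communities generated here, where the species partition, gene content,
and planted read abundances are known exactly.

What is emulated
----------------
* **Species pangenomes** — a shared core gene set plus an accessory pool
  whose genes occur independently in each genome at a set frequency.
* **Genome degradation** — each true gene survives with probability equal
  to the genome's completeness; contamination adds foreign genes.
* **Sequence divergence** — each genome derives from a per-species
  ancestral sequence by independent substitutions at per-base rate
  (100 − within_ani)/200, so a pair of members diverges at roughly
  (100 − within_ani)% in total; different species are independent random
  sequences (~random k-mer overlap, far below any species threshold).
* **Metagenome samples** — single-end reads drawn from genomes in
  proportion to planted abundances; the remainder comes from a background
  sequence rejection-checked to share no 31-mers with any genome, so the
  unmapped fraction is meaningful.

Substitution-only (no indels), single-end, no quality model — enough to
exercise exact-match mapping and k-mer ANI, no more.  Gene content and
nucleotide sequence are generated independently: the gene analysis runs
on annotation-derived presence tables, not coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ani import canonical_kmer_codes
from .seqio import revcomp, stable_label_seed, write_fasta, write_fastq

__all__ = [
    "SpeciesSpec",
    "SiteSpec",
    "TruthSet",
    "generate_pangenome",
    "degrade_genome",
    "generate_sequences",
    "generate_reads",
    "generate_community",
    "Community",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SpeciesSpec:
    """Parameters of one synthetic species.

    accessory_freq may be a single frequency applied to the whole
    accessory pool or a per-gene vector of length n_accessory_pool.
    within_ani is the target pairwise nucleotide identity (percent)
    between member genomes.
    """

    species_id: str
    n_core_genes: int
    n_accessory_pool: int
    accessory_freq: float | Sequence[float]
    genome_length: int
    n_genomes: int
    within_ani: float = 98.0

    def __post_init__(self) -> None:
        if self.n_core_genes < 1:
            raise ValueError(f"{self.species_id}: n_core_genes must be ≥ 1")
        if self.n_accessory_pool < 0:
            raise ValueError(f"{self.species_id}: n_accessory_pool must be ≥ 0")
        for f in self.freq_vector():
            if not 0.0 < f < 1.0:
                raise ValueError(
                    f"{self.species_id}: accessory_freq must be in (0, 1), got {f}"
                )
        if not 90.0 < self.within_ani <= 100.0:
            raise ValueError(f"{self.species_id}: within_ani must be in (90, 100]")
        if self.n_genomes < 1:
            raise ValueError(f"{self.species_id}: n_genomes must be ≥ 1")
        if self.genome_length < 1:
            raise ValueError(f"{self.species_id}: genome_length must be positive")

    def freq_vector(self) -> np.ndarray:
        if np.isscalar(self.accessory_freq):
            return np.full(self.n_accessory_pool, float(self.accessory_freq))
        freq = np.asarray(self.accessory_freq, dtype=float)
        if freq.shape != (self.n_accessory_pool,):
            raise ValueError(
                f"{self.species_id}: accessory_freq vector must have length "
                f"{self.n_accessory_pool}"
            )
        return freq

    def genome_ids(self) -> list[str]:
        return [f"{self.species_id}_g{j:02d}" for j in range(1, self.n_genomes + 1)]


@dataclass(frozen=True)
class SiteSpec:
    """One sampling site in the site → region → country → continent hierarchy."""

    site_id: str
    region: str
    country: str
    continent: str
    n_samples: int
    planted_abundances: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"{self.site_id}: n_samples must be ≥ 1")
        total = sum(self.planted_abundances.values())
        if any(a < 0 for a in self.planted_abundances.values()) or total > 1.0 + 1e-9:
            raise ValueError(
                f"{self.site_id}: planted abundances must be ≥ 0 and sum to ≤ 1 "
                f"(remainder is unmapped background); got sum {total}"
            )

    def sample_ids(self) -> list[str]:
        return [f"{self.site_id}_s{j:02d}" for j in range(1, self.n_samples + 1)]


@dataclass
class TruthSet:
    """Ground truth of a generated community."""

    true_gene_content: dict[str, set[str]] = field(default_factory=dict)
    true_core_sets: dict[str, set[str]] = field(default_factory=dict)
    true_partition: dict[str, str] = field(default_factory=dict)
    true_abundances: dict[tuple[str, str], float] = field(default_factory=dict)


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), stable_label_seed(label)])


def generate_pangenome(
    spec: SpeciesSpec, seed: int
) -> tuple[list[str], dict[str, set[str]]]:
    """Generate one species' gene catalog and per-genome true gene sets.

    Every genome carries all core genes; each accessory-pool gene occurs
    in each genome independently at its frequency.

    Returns (gene catalog, genome_id → true gene set).
    """
    rng = _rng(seed, f"pangenome:{spec.species_id}")
    core = [f"{spec.species_id}_core{i:05d}" for i in range(spec.n_core_genes)]
    acc = [f"{spec.species_id}_acc{i:05d}" for i in range(spec.n_accessory_pool)]
    freq = spec.freq_vector()
    content: dict[str, set[str]] = {}
    for gid in spec.genome_ids():
        carried = rng.random(spec.n_accessory_pool) < freq
        content[gid] = set(core) | {a for a, keep in zip(acc, carried) if keep}
    return core + acc, content


def degrade_genome(
    true_genes: set[str],
    completeness: float,
    contamination_rate: float,
    foreign_pool: Iterable[str],
    seed: int,
) -> set[str]:
    """Degrade a true gene set into an observed (MAG-like) gene set.

    Each true gene is retained independently with probability
    ``completeness``; foreign genes are added at the contamination rate —
    the number of added genes is Binomial(n_true_genes, rate), drawn
    without replacement from ``foreign_pool``.
    """
    if not 0.0 < completeness <= 1.0:
        raise ValueError(f"completeness must be in (0, 1], got {completeness}")
    if not 0.0 <= contamination_rate < 1.0:
        raise ValueError(f"contamination_rate must be in [0, 1), got {contamination_rate}")
    rng = np.random.default_rng(seed)
    genes = sorted(true_genes)
    kept = {g for g in genes if rng.random() < completeness} if completeness < 1.0 else set(genes)
    foreign = sorted(set(foreign_pool) - true_genes)
    if contamination_rate > 0.0 and foreign:
        n_add = min(int(rng.binomial(len(genes), contamination_rate)), len(foreign))
        if n_add:
            picked = rng.choice(len(foreign), size=n_add, replace=False)
            kept |= {foreign[i] for i in picked}
    return kept


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently at ``rate``, always to a different base."""
    if rate <= 0.0:
        return seq.copy()
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < rate)
    if hit.size:
        codes = np.searchsorted(_BASES, out[hit])  # ACGT are sorted bytes
        out[hit] = _BASES[(codes + rng.integers(1, 4, size=hit.size)) % 4]
    return out


def generate_sequences(spec: SpeciesSpec, seed: int) -> dict[str, str]:
    """Genome nucleotide sequences for one species.

    One random ancestral sequence per species (seeded by species_id, so
    different species diverge even under the same top-level seed); each
    member genome applies independent substitutions at per-base rate
    (100 − within_ani)/200, giving expected *pairwise* identity ≈
    within_ani between members.
    """
    rng = _rng(seed, f"sequences:{spec.species_id}")
    ancestor = _random_sequence(rng, spec.genome_length)
    rate = (100.0 - spec.within_ani) / 100.0 / 2.0
    return {
        gid: _mutate(ancestor, rate, rng).tobytes().decode("ascii")
        for gid in spec.genome_ids()
    }


def _background_sequence(
    rng: np.random.Generator, length: int, forbidden_kmers: np.ndarray, k: int = 31,
    max_tries: int = 50,
) -> str:
    """Random sequence sharing no canonical k-mers with the genomes."""
    for _ in range(max_tries):
        cand = _random_sequence(rng, length).tobytes().decode("ascii")
        codes = canonical_kmer_codes(cand, k)
        if forbidden_kmers.size == 0 or not np.intersect1d(
            codes, forbidden_kmers, assume_unique=True
        ).size:
            return cand
    raise RuntimeError("could not generate a background sequence disjoint from the genomes")


def generate_reads(
    genomes: Mapping[str, str],
    site: SiteSpec,
    read_length: int = 150,
    n_reads: int = 100_000,
    error_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, list[tuple[str, str]]]:
    """Simulate single-end read sets for every sample of a site.

    ``site.planted_abundances`` keys must be keys of ``genomes`` (one
    reference sequence per planted population).  Each read picks its
    source by the planted abundances (remainder: background), a uniform
    start position, a uniform strand, and per-base substitution errors at
    ``error_rate``.  Read ids encode the source as ``...|src=<label>`` so
    recovery tests can check assignments.

    Returns sample_id → list of (read_id, sequence).
    """
    if n_reads <= 0:
        raise ValueError(f"n_reads must be positive, got {n_reads}")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError(f"error_rate must be in [0, 1), got {error_rate}")
    missing = sorted(set(site.planted_abundances) - set(genomes))
    if missing:
        raise ValueError(f"planted abundances refer to unknown genomes: {missing}")
    short = [g for g in site.planted_abundances if len(genomes[g]) < read_length]
    if short:
        raise ValueError(f"read_length {read_length} exceeds genome length for: {short}")

    labels = sorted(site.planted_abundances)
    probs = np.array([site.planted_abundances[g] for g in labels])
    background_prob = max(0.0, 1.0 - probs.sum())
    sources = {g: np.frombuffer(genomes[g].encode("ascii"), dtype=np.uint8) for g in labels}

    rng = _rng(seed, f"reads:{site.site_id}")
    if background_prob > 0.0:
        length = max(max((len(genomes[g]) for g in labels), default=read_length), read_length)
        forbidden = np.unique(
            np.concatenate(
                [canonical_kmer_codes(genomes[g], 31) for g in labels]
                or [np.empty(0, dtype=np.uint64)]
            )
        )
        bg = _background_sequence(rng, length, forbidden)
        sources["background"] = np.frombuffer(bg.encode("ascii"), dtype=np.uint8)
        labels = labels + ["background"]
        probs = np.append(probs, background_prob)
    probs = probs / probs.sum()

    out: dict[str, list[tuple[str, str]]] = {}
    for sample_id in site.sample_ids():
        srng = _rng(seed, f"reads:{site.site_id}:{sample_id}")
        choice = srng.choice(len(labels), size=n_reads, p=probs)
        reads: list[tuple[str, str]] = []
        for i, src_idx in enumerate(choice):
            label = labels[src_idx]
            seq = sources[label]
            start = int(srng.integers(0, len(seq) - read_length + 1))
            frag = seq[start : start + read_length]
            frag = _mutate(frag, error_rate, srng)
            read = frag.tobytes().decode("ascii")
            if srng.random() < 0.5:
                read = revcomp(read)
            reads.append((f"{sample_id}_r{i:06d}|src={label}", read))
        out[sample_id] = reads
    return out


@dataclass
class Community:
    """A fully generated synthetic community plus its ground truth."""

    species: list[SpeciesSpec]
    sites: list[SiteSpec]
    sequences: dict[str, str]  # genome_id → nucleotide sequence
    observed_genes: dict[str, set[str]]  # after degradation
    gene_catalog: list[str]
    completeness: dict[str, float]  # fraction per genome
    contamination: dict[str, float]  # rate per genome
    reads: dict[str, list[tuple[str, str]]]  # sample_id → reads
    truth: TruthSet

    def genome_metadata(self) -> pd.DataFrame:
        """Genome metadata table; genome origin = first site planting its species."""
        site_of_species: dict[str, SiteSpec] = {}
        for site in self.sites:
            for sp in site.planted_abundances:
                site_of_species.setdefault(sp, site)
        rows = []
        for gid in sorted(self.sequences):
            sp = self.truth.true_partition[gid]
            site = site_of_species.get(sp)
            rows.append(
                {
                    "genome_id": gid,
                    "completeness": round(self.completeness[gid] * 100.0, 3),
                    "contamination": round(self.contamination[gid] * 100.0, 3),
                    "site": site.site_id if site else "",
                    "region": site.region if site else "",
                    "country": site.country if site else "",
                    "continent": site.continent if site else "",
                    "kind": "MAG",
                }
            )
        return pd.DataFrame(rows)

    def sample_metadata(self) -> pd.DataFrame:
        rows = []
        for site in self.sites:
            for sample_id in site.sample_ids():
                rows.append(
                    {
                        "sample_id": sample_id,
                        "site_id": site.site_id,
                        "region": site.region,
                        "country": site.country,
                        "continent": site.continent,
                    }
                )
        return pd.DataFrame(rows)

    def presence_matrix(self) -> pd.DataFrame:
        """Observed 0/1 gene presence, rows = gene clusters, columns = genomes."""
        genomes = sorted(self.observed_genes)
        data = {
            g: [1 if gene in self.observed_genes[g] else 0 for gene in self.gene_catalog]
            for g in genomes
        }
        return pd.DataFrame(data, index=self.gene_catalog)

    def write(self, outdir: str | Path) -> None:
        """Write the community as plain-text files (FASTA/FASTQ/TSV)."""
        outdir = Path(outdir)
        (outdir / "genomes").mkdir(parents=True, exist_ok=True)
        (outdir / "reads").mkdir(parents=True, exist_ok=True)
        for gid, seq in self.sequences.items():
            write_fasta(outdir / "genomes" / f"{gid}.fasta", {gid: seq})
        for sample_id, reads in self.reads.items():
            write_fastq(outdir / "reads" / f"{sample_id}.fastq", reads)
        self.genome_metadata().to_csv(outdir / "genome_metadata.tsv", sep="\t", index=False)
        self.sample_metadata().to_csv(outdir / "sample_metadata.tsv", sep="\t", index=False)
        self.presence_matrix().rename_axis("gene").to_csv(outdir / "gene_presence.tsv", sep="\t")
        pd.DataFrame(
            [(g, s) for g, s in sorted(self.truth.true_partition.items())],
            columns=["genome_id", "species_id"],
        ).to_csv(outdir / "truth_partition.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(smp, sp, a) for (smp, sp), a in sorted(self.truth.true_abundances.items())],
            columns=["sample_id", "species_id", "abundance"],
        ).to_csv(outdir / "truth_abundances.tsv", sep="\t", index=False)


def generate_community(
    species: Sequence[SpeciesSpec],
    sites: Sequence[SiteSpec],
    seed: int,
    completeness: Mapping[str, float] | float = 0.9,
    contamination_rate: Mapping[str, float] | float = 0.0,
    read_length: int = 150,
    reads_per_sample: int = 100_000,
    error_rate: float = 0.0,
) -> Community:
    """Generate a full community: pangenomes, sequences, degraded gene
    sets, and per-sample reads, with ground truth.

    ``completeness``/``contamination_rate`` may be one value for every
    genome or a per-genome mapping (no distributional assumption is
    imposed).  Reads for a planted species are drawn from its first
    member genome's sequence.
    """
    ids = [sp.species_id for sp in species]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate species_id in species list")
    truth = TruthSet()
    sequences: dict[str, str] = {}
    observed: dict[str, set[str]] = {}
    catalog: list[str] = []
    comp_map: dict[str, float] = {}
    contam_map: dict[str, float] = {}

    contents: dict[str, dict[str, set[str]]] = {}
    for sp in species:
        genes, content = generate_pangenome(sp, seed)
        catalog.extend(genes)
        contents[sp.species_id] = content
        truth.true_core_sets[sp.species_id] = {g for g in genes if "_core" in g}
        sequences.update(generate_sequences(sp, seed))

    all_genes = set(catalog)
    for sp in species:
        content = contents[sp.species_id]
        species_genes = {g for gs in content.values() for g in gs} | {
            g for g in all_genes if g.startswith(f"{sp.species_id}_")
        }
        foreign = sorted(all_genes - species_genes)
        for gid, true_genes in content.items():
            truth.true_gene_content[gid] = true_genes
            truth.true_partition[gid] = sp.species_id
            comp = completeness if np.isscalar(completeness) else completeness[gid]
            contam = (contamination_rate if np.isscalar(contamination_rate)
                      else contamination_rate[gid])
            comp_map[gid] = float(comp)
            contam_map[gid] = float(contam)
            observed[gid] = degrade_genome(
                true_genes, float(comp), float(contam), foreign,
                seed=(stable_label_seed(gid) ^ int(seed)) & 0x7FFFFFFF,
            )

    reference_of = {sp.species_id: sp.genome_ids()[0] for sp in species}
    reads: dict[str, list[tuple[str, str]]] = {}
    for site in sites:
        unknown = sorted(set(site.planted_abundances) - set(reference_of))
        if unknown:
            raise ValueError(f"{site.site_id}: planted abundances for unknown species {unknown}")
        ref_site = SiteSpec(
            site_id=site.site_id, region=site.region, country=site.country,
            continent=site.continent, n_samples=site.n_samples,
            planted_abundances={reference_of[s]: a for s, a in site.planted_abundances.items()},
        )
        site_reads = generate_reads(
            sequences, ref_site, read_length=read_length, n_reads=reads_per_sample,
            error_rate=error_rate, seed=seed,
        )
        reads.update(site_reads)
        for sample_id in site.sample_ids():
            for sp_id, a in site.planted_abundances.items():
                truth.true_abundances[(sample_id, sp_id)] = float(a)

    return Community(
        species=list(species), sites=list(sites), sequences=sequences,
        observed_genes=observed, gene_catalog=catalog, completeness=comp_map,
        contamination=contam_map, reads=reads, truth=truth,
    )
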