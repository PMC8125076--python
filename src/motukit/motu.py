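"""Clustering genomes into species-level mOTUs.

A mOTU (metagenomic operational taxonomic unit) is a connected component
of genomes linked by pairwise ANI above a species threshold
(conventionally 95%).  Genome quality gates the clustering in two tiers:

* **seed** genomes (completeness ≥ 70%, contamination ≤ 5%) form the
  graph whose connected components define the mOTUs;
* **recruited** genomes (50% ≤ completeness < 70%, contamination ≤ 5%)
  are attached to an existing mOTU when they share above-threshold ANI
  with at least one of its seed members;
* everything else — and recruits with no qualifying link — is retained
  as **excluded** with a reason code, never silently dropped.

The representative of each mOTU is its most complete seed member.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .ani import ANITable

__all__ = [
    "GenomeRecord",
    "MOTUCatalog",
    "cluster_motus",
    "select_representative",
    "read_genome_metadata",
]

GENOME_KINDS = ("MAG", "SAG", "isolate")


@dataclass(frozen=True)
class GenomeRecord:
    """One genome with quality scores and its source-location path."""

    genome_id: str
    completeness: float  # percent in (0, 100]
    contamination: float  # percent in [0, 100)
    site: str = ""
    region: str = ""
    country: str = ""
    continent: str = ""
    kind: str = "MAG"
    sequence_path: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.completeness <= 100.0:
            raise ValueError(
                f"{self.genome_id}: completeness must be in (0, 100], got {self.completeness}"
            )
        if not 0.0 <= self.contamination < 100.0:
            raise ValueError(
                f"{self.genome_id}: contamination must be in [0, 100), got {self.contamination}"
            )
        if self.kind not in GENOME_KINDS:
            raise ValueError(f"{self.genome_id}: kind must be one of {GENOME_KINDS}")


@dataclass
class MOTUCatalog:
    """Partition of non-excluded genomes into mOTUs.

    ``tier`` maps every input genome to seed/recruited/excluded;
    ``exclusion_reason`` explains the excluded ones
    (low_completeness, high_contamination, unrecruited).
    """

    motus: dict[str, list[str]] = field(default_factory=dict)
    representative: dict[str, str] = field(default_factory=dict)
    tier: dict[str, str] = field(default_factory=dict)
    exclusion_reason: dict[str, str] = field(default_factory=dict)

    def motu_of(self) -> dict[str, str]:
        """Invert ``motus`` into a genome_id → motu_id map."""
        return {g: m for m, members in self.motus.items() for g in members}

    def to_frame(self) -> pd.DataFrame:
        motu_of = self.motu_of()
        rows = []
        for g in sorted(self.tier):
            motu = motu_of.get(g, "")
            rows.append(
                {
                    "genome_id": g,
                    "motu_id": motu,
                    "tier": self.tier[g],
                    "is_representative": self.representative.get(motu) == g,
                    "exclusion_reason": self.exclusion_reason.get(g, ""),
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_json(self, path: str | Path) -> None:
        payload = {
            motu: {
                "members": members,
                "representative": self.representative[motu],
                "tiers": {g: self.tier[g] for g in members},
            }
            for motu, members in self.motus.items()
        }
        payload["excluded"] = {
            g: self.exclusion_reason[g] for g, t in self.tier.items() if t == "excluded"
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MOTUCatalog":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        cat = cls()
        for _, row in df.iterrows():
            cat.tier[row["genome_id"]] = row["tier"]
            if row["motu_id"]:
                cat.motus.setdefault(row["motu_id"], []).append(row["genome_id"])
                if str(row["is_representative"]) == "True":
                    cat.representative[row["motu_id"]] = row["genome_id"]
            if row.get("exclusion_reason", ""):
                cat.exclusion_reason[row["genome_id"]] = row["exclusion_reason"]
        cat.motus = {m: sorted(v) for m, v in sorted(cat.motus.items())}
        return cat


def select_representative(members: Sequence[str], genomes: Mapping[str, GenomeRecord],
                          tier: Mapping[str, str]) -> str:
    """Most complete seed-tier member; ties by lowest contamination, then id."""
    seeds = [g for g in members if tier[g] == "seed"]
    if not seeds:
        raise RuntimeError("internal invariant violated: mOTU without seed members")
    return min(seeds, key=lambda g: (-genomes[g].completeness, genomes[g].contamination, g))


def cluster_motus(
    ani: ANITable,
    genomes: Iterable[GenomeRecord],
    ani_threshold: float = 95.0,
    comp_seed_min: float = 70.0,
    comp_recruit_min: float = 50.0,
    contam_max: float = 5.0,
    strict_above: bool = True,
) -> MOTUCatalog:
    """Cluster genomes into mOTUs by two-tier ANI connected components.

    Genome pairs with ANI above ``ani_threshold`` ("above" is strictly
    greater by default; set ``strict_above=False`` for ≥) are edges in a
    graph over the seed-quality genomes; connected components, singletons
    included, become mOTUs.  Lower-completeness genomes are recruited to
    the component with which they share an above-threshold link to a seed
    member — if several qualify, to the one with the highest mean ANI to
    its seeds, ties broken deterministically.  mOTU ids are assigned by
    decreasing member count, then by lexicographically smallest member.
    """
    if not comp_recruit_min < comp_seed_min:
        raise ValueError("comp_recruit_min must be below comp_seed_min")
    records = {g.genome_id: g for g in genomes}
    if len(records) == 0:
        return MOTUCatalog()

    def above(x: float) -> bool:
        return x > ani_threshold if strict_above else x >= ani_threshold

    if ani.provenance == "imported":
        missing = sorted(set(records) - ani.genome_ids())
        if missing:
            warnings.warn(
                f"{len(missing)} genome(s) absent from the imported ANI table "
                f"(treated as having no above-threshold pairs): {missing[:5]}...",
                stacklevel=2,
            )

    catalog = MOTUCatalog()
    seeds, recruits = [], []
    for gid, rec in sorted(records.items()):
        if rec.contamination > contam_max:
            catalog.tier[gid] = "excluded"
            catalog.exclusion_reason[gid] = "high_contamination"
        elif rec.completeness >= comp_seed_min:
            catalog.tier[gid] = "seed"
            seeds.append(gid)
        elif rec.completeness >= comp_recruit_min:
            recruits.append(gid)  # tier decided after recruitment
        else:
            catalog.tier[gid] = "excluded"
            catalog.exclusion_reason[gid] = "low_completeness"

    graph = nx.Graph()
    graph.add_nodes_from(seeds)
    for i, a in enumerate(seeds):
        for b in seeds[i + 1 :]:
            if above(ani.get(a, b)):
                graph.add_edge(a, b)
    # keyed by smallest seed member until final ids are assigned
    clusters: dict[str, list[str]] = {
        min(comp): sorted(comp) for comp in nx.connected_components(graph)
    }

    for gid in recruits:
        candidates = []
        for key, members in clusters.items():
            seed_members = [m for m in members if catalog.tier[m] == "seed"]
            links = [ani.get(gid, m) for m in seed_members]
            if any(above(x) for x in links):
                mean_ani = sum(links) / len(links)
                candidates.append((-mean_ani, key))
        if candidates:
            _, key = min(candidates)  # highest mean ANI, then smallest key
            clusters[key].append(gid)
            catalog.tier[gid] = "recruited"
        else:
            catalog.tier[gid] = "excluded"
            catalog.exclusion_reason[gid] = "unrecruited"

    ordered = sorted(clusters.values(), key=lambda ms: (-len(ms), min(ms)))
    width = max(2, len(str(len(ordered))))
    for idx, members in enumerate(ordered, start=1):
        motu_id = f"mOTU{idx:0{width}d}"
        catalog.motus[motu_id] = sorted(members)
        catalog.representative[motu_id] = select_representative(members, records, catalog.tier)
    return catalog


def read_genome_metadata(path: str | Path) -> list[GenomeRecord]:
    """Read the genome metadata TSV.

    Expected columns: genome_id, completeness, contamination and
    optionally site, region, country, continent, kind, sequence_path.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"genome_id", "completeness", "contamination"}
    if not required <= set(df.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            GenomeRecord(
                genome_id=row["genome_id"],
                completeness=float(row["completeness"]),
                contamination=float(row["contamination"]),
                site=row.get("site", ""),
                region=row.get("region", ""),
                country=row.get("country", ""),
                continent=row.get("continent", ""),
                kind=row.get("kind", "MAG") or "MAG",
                sequence_path=row.get("sequence_path") or None,
            )
        )
    return out
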