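"""Geographic classification of mOTUs: cosmopolitan, regional, endemic.

Two evidence channels establish where a mOTU occurs:

* the source locations of its member genomes (where the MAGs/SAGs were
  assembled from), and
* the sites where read-mapping occupancy calls it present.

Both are mapped through the caller-supplied site → region → country →
continent hierarchy (geography is metadata, never hardcoded) and their
union classified:

* **cosmopolitan** — evidence spans ≥ 2 continents;
* **endemic** — all evidence falls within a single region (hence also a
  single site when only one site is seen);
* **regional** — anything in between (one continent, several regions);
* **unknown** — no located genomes and no occupancy evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .abundance import OccupancyTable
from .motu import GenomeRecord, MOTUCatalog

__all__ = ["BiogeographyTable", "classify_biogeography", "site_hierarchy_from_meta"]


def site_hierarchy_from_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Unique site → region/country/continent rows from any metadata table."""
    cols = ["region", "country", "continent"]
    site_col = "site" if "site" in meta.columns else "site_id"
    hier = meta[[site_col] + cols].rename(columns={site_col: "site_id"})
    hier = hier[hier["site_id"] != ""].drop_duplicates("site_id")
    return hier.reset_index(drop=True)


@dataclass
class BiogeographyTable:
    """Per-mOTU classification plus the evidence that produced it."""

    table: pd.DataFrame  # motu_id, classification, continents, regions, sites,
    # genome_sites, occupancy_sites

    def classification(self) -> dict[str, str]:
        return dict(zip(self.table["motu_id"], self.table["classification"]))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _classify(continents: set[str], regions: set[str]) -> str:
    if not continents and not regions:
        return "unknown"
    if len(continents) >= 2:
        return "cosmopolitan"
    if len(regions) <= 1:
        return "endemic"
    return "regional"


def classify_biogeography(
    catalog: MOTUCatalog,
    genome_meta: Iterable[GenomeRecord],
    occupancy: OccupancyTable | None = None,
    site_hierarchy: pd.DataFrame | None = None,
) -> BiogeographyTable:
    """Classify every mOTU's distribution from genomes and occupancy.

    ``site_hierarchy`` (site_id, region, country, continent) resolves
    occupancy sites; when omitted it is derived from the genome records.
    Occupancy contributes only (mOTU, site) pairs flagged present.
    """
    records: Mapping[str, GenomeRecord] = {g.genome_id: g for g in genome_meta}
    if site_hierarchy is None:
        rows = [
            {"site_id": g.site, "region": g.region, "country": g.country,
             "continent": g.continent}
            for g in records.values() if g.site
        ]
        site_hierarchy = pd.DataFrame(
            rows, columns=["site_id", "region", "country", "continent"]
        ).drop_duplicates("site_id")
    hier = site_hierarchy.set_index("site_id")

    present_sites: dict[str, set[str]] = {}
    if occupancy is not None:
        present = occupancy.table[occupancy.table["present"]]
        for _, row in present.iterrows():
            present_sites.setdefault(row["motu_id"], set()).add(row["site_id"])

    rows = []
    for motu_id, members in catalog.motus.items():
        genome_sites = {records[g].site for g in members if g in records and records[g].site}
        occ_sites = present_sites.get(motu_id, set())
        sites = genome_sites | occ_sites
        regions, continents = set(), set()
        for g in members:
            rec = records.get(g)
            if rec and (rec.region or rec.continent):
                if rec.region:
                    regions.add(rec.region)
                if rec.continent:
                    continents.add(rec.continent)
        unknown_sites = sorted(s for s in occ_sites if s not in hier.index)
        if unknown_sites:
            raise ValueError(
                f"{motu_id}: occupancy sites missing from the site hierarchy: "
                f"{unknown_sites[:5]}"
            )
        for s in occ_sites:
            regions.add(hier.loc[s, "region"])
            continents.add(hier.loc[s, "continent"])
        regions.discard("")
        continents.discard("")
        rows.append(
            {
                "motu_id": motu_id,
                "classification": _classify(continents, regions),
                "continents": ";".join(sorted(continents)),
                "regions": ";".join(sorted(regions)),
                "sites": ";".join(sorted(sites)),
                "genome_sites": ";".join(sorted(genome_sites)),
                "occupancy_sites": ";".join(sorted(occ_sites)),
            }
        )
    return BiogeographyTable(table=pd.DataFrame(rows))
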