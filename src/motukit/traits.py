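"""Metabolic-marker trait matrices: core / accessory / absent per mOTU.

Marker-gene hits (e.g. Diamond/BLAST searches of PsaA, Sqr, DsrA, SoxB,
Cyc2, HyaB, HyhL, NifH, FCC, AclB against per-marker databases) are
filtered by query coverage (default ≥ 80%) and percent identity
(default ≥ 50%, with per-marker overrides such as 80% for PsaA).  A
marker is *absent* from a mOTU only when no member genome carries it
after filtering — absence across every MAG and SAG of the cluster is the
evidence standard.  Otherwise the marker's presence profile across the
mOTU's genomes is placed on the fitted core/accessory scale of the
mOTU's pangenome partition (same likelihood rule, same carriage
probabilities), never a bare frequency heuristic.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .motu import MOTUCatalog
from .pangenome import GenePartitionResults

__all__ = [
    "read_hit_table",
    "read_blast_hits",
    "filter_hits",
    "trait_status",
    "build_trait_matrix",
]

#: default inclusive thresholds
COVERAGE_MIN = 80.0
IDENTITY_MIN_DEFAULT = 50.0
#: markers requiring the stricter identity threshold
IDENTITY_MIN_OVERRIDES = {"PsaA": 80.0}

HIT_COLUMNS = ["genome_id", "marker", "identity", "coverage"]

BLAST12_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read the pre-reduced 4-column hit TSV (genome_id, marker, identity, coverage)."""
    df = pd.read_csv(path, sep="\t")
    if not set(HIT_COLUMNS) <= set(df.columns):
        raise ValueError(f"hit table must have columns {HIT_COLUMNS}")
    return df[HIT_COLUMNS]


def read_blast_hits(
    path: str | Path,
    query_lengths: Mapping[str, int],
    marker_of_subject: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Reduce a 12-column tabular alignment file to the 4-column hit table.

    Query ids are genome ids; subject ids name the marker database entry
    (mapped through ``marker_of_subject`` when given, otherwise used as
    the marker name directly).  Query coverage is computed against the
    *query* length: 100 · (qend − qstart + 1) / query_length.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST12_COLUMNS)
    missing = sorted(set(df["qseqid"]) - set(query_lengths))
    if missing:
        raise ValueError(f"no query length for: {missing[:5]}")
    qlen = df["qseqid"].map(query_lengths)
    coverage = 100.0 * (df["qend"] - df["qstart"] + 1).abs() / qlen
    marker = df["sseqid"].map(marker_of_subject) if marker_of_subject else df["sseqid"]
    if marker.isna().any():
        bad = sorted(df.loc[marker.isna(), "sseqid"].unique())
        raise ValueError(f"subjects without a marker mapping: {bad[:5]}")
    return pd.DataFrame(
        {
            "genome_id": df["qseqid"],
            "marker": marker,
            "identity": df["pident"],
            "coverage": coverage,
        }
    )


def filter_hits(
    hits: pd.DataFrame,
    coverage_min: float = COVERAGE_MIN,
    identity_min: Mapping[str, float] | None = None,
    identity_min_default: float | None = IDENTITY_MIN_DEFAULT,
) -> pd.DataFrame:
    """Reduce hits to per-(genome, marker) presence flags.

    A marker is present in a genome iff at least one hit passes both the
    coverage and the marker's identity threshold; both comparisons are
    inclusive (≥).  ``identity_min`` overrides the default per marker
    (the stock overrides require 80% for PsaA); with
    ``identity_min_default=None`` every marker in the table must have an
    explicit threshold.

    Returns a boolean DataFrame, rows = genome ids, columns = markers.
    """
    thresholds = dict(IDENTITY_MIN_OVERRIDES)
    if identity_min:
        thresholds.update(identity_min)
    markers = sorted(hits["marker"].unique())
    if identity_min_default is None:
        unknown = [m for m in markers if m not in thresholds]
        if unknown:
            raise ValueError(f"no identity threshold for markers: {unknown}")
    ident_min = hits["marker"].map(
        lambda m: thresholds.get(m, identity_min_default)
    ).astype(float)
    passing = hits[(hits["coverage"] >= coverage_min) & (hits["identity"] >= ident_min)]
    genomes = sorted(hits["genome_id"].unique())
    presence = pd.DataFrame(False, index=genomes, columns=markers)
    for _, row in passing.iterrows():
        presence.loc[row["genome_id"], row["marker"]] = True
    return presence


def trait_status(
    marker_presence: Mapping[str, bool],
    members: Sequence[str],
    fit: GenePartitionResults,
) -> str:
    """Status of one marker in one mOTU: ``core``/``accessory``/``absent``.

    ``marker_presence`` maps genome_id → carries-the-marker; members
    missing from it are treated as not carrying it (with a warning
    handled by the caller).  Absent only if *no* member carries the
    marker; otherwise the profile is classified with the mOTU's fitted
    likelihood rule.
    """
    profile = {g: int(bool(marker_presence.get(g, False))) for g in members}
    if sum(profile.values()) == 0:
        return "absent"
    status, _, _ = fit.classify_profile(profile)
    return status


def build_trait_matrix(
    presence: pd.DataFrame,
    catalog: MOTUCatalog,
    fits: Mapping[str, GenePartitionResults],
) -> pd.DataFrame:
    """Trait matrix over all mOTUs: rows = motu_id, columns = markers.

    ``presence`` is the boolean genome × marker frame from
    :func:`filter_hits`.  Member genomes missing from it are treated as
    lacking every marker (warned once per mOTU).
    """
    rows = {}
    for motu_id, members in catalog.motus.items():
        if motu_id not in fits:
            raise ValueError(f"no fitted partition for {motu_id}")
        missing = [g for g in members if g not in presence.index]
        if missing:
            warnings.warn(
                f"{motu_id}: {len(missing)} member genome(s) absent from the marker "
                f"presence table, treated as lacking all markers: {missing[:3]}",
                stacklevel=2,
            )
        rows[motu_id] = {
            marker: trait_status(presence[marker].to_dict(), members, fits[motu_id])
            for marker in presence.columns
        }
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "motu_id"
    return out
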