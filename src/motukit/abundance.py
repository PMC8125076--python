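"""mOTU abundance profiles by subsampled, 100%-identity competitive mapping.

Each metagenome is subsampled to a fixed read count (1,000,000 by
default), every read is matched against *all* genomes of *all* mOTUs at
100% identity (full-length exact substring of a genome or its reverse
complement — no mismatches, no clipping), and matches are resolved
competitively:

* a read matching genomes of exactly one mOTU counts 1 for that mOTU;
* a read matching genomes of k > 1 mOTUs counts 1/k for each (equal
  split; deterministic and conservation-preserving — ``discard`` and
  seeded ``random`` policies are available);
* a read matching nothing goes to the unmapped tally.

Counts are kept as exact fractions so that per-sample mOTU abundances
plus the unmapped fraction sum to 1 exactly.  Per-sample relative
abundances are count / subsample size; per-site occupancy is the
unweighted arithmetic mean over the site's samples (zeros included),
with presence called at a relative-abundance cutoff (0.03% = 0.0003 by
default, boundary inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ani import canonical_kmer_codes
from .seqio import revcomp

__all__ = [
    "subsample_reads",
    "ExactMatchIndex",
    "competitive_assign",
    "relative_abundance",
    "AbundanceMatrix",
    "OccupancyTable",
    "aggregate_by_location",
    "apply_presence_cutoff",
    "profile_samples",
]

SEED_K = 31  # k-mer size used to seed candidate lookups before full-read verification


def subsample_reads(
    reads: Sequence[tuple[str, str]], target: int = 1_000_000, seed: int = 0
) -> list[tuple[str, str]]:
    """Uniform sample without replacement of ``min(target, len(reads))`` reads.

    Emits a warning when the library is smaller than the target (the
    whole library is then returned).
    """
    if target <= 0:
        raise ValueError(f"subsample target must be positive, got {target}")
    if len(reads) == 0:
        raise ValueError("cannot subsample an empty read set")
    if len(reads) <= target:
        if len(reads) < target:
            warnings.warn(
                f"library has {len(reads)} reads, below the subsample target {target}; "
                "using all reads", stacklevel=2,
            )
        return list(reads)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=target, replace=False)
    return [reads[i] for i in np.sort(idx)]


class ExactMatchIndex:
    """Exact full-length read matcher over a genome collection.

    Candidate genomes are found through a canonical 31-mer seed taken
    from the read's first window, then verified by exact substring search
    against the genome or its reverse complement, which implements the
    100%-identity criterion precisely.
    """

    def __init__(self, genomes: Mapping[str, str], read_length: int):
        if read_length < SEED_K:
            raise ValueError(f"read_length must be ≥ {SEED_K}, got {read_length}")
        self.read_length = read_length
        self._fwd: dict[str, str] = {}
        self._rev: dict[str, str] = {}
        self._candidates: dict[int, list[str]] = {}
        for gid in sorted(genomes):
            seq = genomes[gid].upper()
            if len(seq) < read_length:
                warnings.warn(
                    f"genome {gid} is shorter than the read length and can never "
                    "match full-length reads", stacklevel=2,
                )
            self._fwd[gid] = seq
            self._rev[gid] = revcomp(seq)
            if len(seq) >= SEED_K:
                for code in canonical_kmer_codes(seq, SEED_K):
                    bucket = self._candidates.setdefault(int(code), [])
                    if not bucket or bucket[-1] != gid:
                        bucket.append(gid)

    def match(self, read: str) -> frozenset[str]:
        """Genomes containing the read (or its reverse complement) exactly."""
        read = read.upper()
        if len(read) < SEED_K:
            return frozenset()
        try:
            seed_codes = canonical_kmer_codes(read[:SEED_K], SEED_K)
        except ValueError:
            return frozenset()
        if seed_codes.size == 0:
            return frozenset()
        candidates = self._candidates.get(int(seed_codes[0]))
        if not candidates:
            return frozenset()
        hits = [g for g in candidates if read in self._fwd[g] or read in self._rev[g]]
        return frozenset(hits)


def competitive_assign(
    matches: Iterable[frozenset[str]],
    genome_to_motu: Mapping[str, str],
    ambiguous: str = "split",
    seed: int = 0,
) -> tuple[dict[str, Fraction], Fraction]:
    """Resolve per-read genome matches into per-mOTU read counts.

    ``ambiguous`` controls reads matching more than one mOTU:
    ``split`` (default) gives 1/k to each of the k mOTUs, ``discard``
    sends them to the unmapped tally, ``random`` assigns the whole read
    to one of the k uniformly (seeded).  Counts are exact fractions;
    their total plus the unmapped tally equals the number of reads.
    """
    if ambiguous not in ("split", "discard", "random"):
        raise ValueError(f"unknown ambiguous-read policy: {ambiguous!r}")
    rng = np.random.default_rng(seed)
    counts: dict[str, Fraction] = {}
    unmapped = Fraction(0)
    for match in matches:
        if not match:
            unmapped += 1
            continue
        motus = set()
        for g in match:
            if g not in genome_to_motu:
                raise RuntimeError(
                    f"matched genome {g} has no mOTU assignment; excluded genomes "
                    "must not be in the match index"
                )
            motus.add(genome_to_motu[g])
        if len(motus) == 1:
            (m,) = motus
            counts[m] = counts.get(m, Fraction(0)) + 1
        elif ambiguous == "split":
            share = Fraction(1, len(motus))
            for m in motus:
                counts[m] = counts.get(m, Fraction(0)) + share
        elif ambiguous == "discard":
            unmapped += 1
        else:  # random
            m = sorted(motus)[int(rng.integers(0, len(motus)))]
            counts[m] = counts.get(m, Fraction(0)) + 1
    return counts, unmapped


def relative_abundance(
    counts: Mapping[str, Fraction | float], n_subsampled: int
) -> dict[str, float]:
    """Normalise per-mOTU read counts to relative abundances (count / n)."""
    if n_subsampled <= 0:
        raise ValueError("n_subsampled must be positive")
    total = sum(counts.values())
    if total > n_subsampled:
        raise ValueError(
            f"counts sum to {float(total)} which exceeds the subsample size {n_subsampled}"
        )
    return {m: float(Fraction(c) / n_subsampled) for m, c in counts.items()}


@dataclass
class AbundanceMatrix:
    """mOTU × sample relative abundances plus per-sample unmapped fraction."""

    values: pd.DataFrame  # rows = motu_id, columns = sample_id
    unmapped: pd.Series  # per sample
    subsample_size: int
    seed: int
    exact_counts: dict[str, dict[str, Fraction]] = field(default_factory=dict)
    exact_unmapped: dict[str, Fraction] = field(default_factory=dict)
    n_subsampled: dict[str, int] = field(default_factory=dict)

    def conservation_check(self) -> pd.Series:
        """Per-sample Σ abundance + unmapped fraction.

        Computed on the exact fractional counts where available, so the
        result is 1 exactly (not merely to float rounding).
        """
        out = {}
        for s in self.values.columns:
            if s in self.exact_counts and s in self.n_subsampled:
                total = sum(self.exact_counts[s].values(), Fraction(0))
                total += self.exact_unmapped.get(s, Fraction(0))
                out[s] = float(Fraction(total, self.n_subsampled[s]))
            else:
                out[s] = float(self.values[s].sum() + self.unmapped[s])
        return pd.Series(out)

    def to_long(self) -> pd.DataFrame:
        long = self.values.rename_axis("motu_id").reset_index().melt(
            id_vars="motu_id", var_name="sample_id", value_name="abundance"
        )
        return long.sort_values(["motu_id", "sample_id"]).reset_index(drop=True)

    def write(self, outdir: str | Path, prefix: str = "abundance") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.values.rename_axis("motu_id").to_csv(outdir / f"{prefix}_wide.tsv", sep="\t")
        self.to_long().to_csv(outdir / f"{prefix}_long.tsv", sep="\t", index=False)
        self.unmapped.rename("unmapped_fraction").rename_axis("sample_id").to_csv(
            outdir / f"{prefix}_unmapped.tsv", sep="\t"
        )


@dataclass
class OccupancyTable:
    """Per-(mOTU, site) mean abundance and presence call."""

    table: pd.DataFrame  # columns: motu_id, site_id, mean_abundance, n_samples, present
    cutoff: float

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def aggregate_by_location(
    matrix: AbundanceMatrix, sample_meta: pd.DataFrame, cutoff: float = 0.0003
) -> OccupancyTable:
    """Average per-sample abundances over each site and call presence.

    The mean is the unweighted arithmetic mean over *all* of the site's
    samples in the matrix, zeros included.  Every sample column must
    appear in ``sample_meta`` (columns sample_id, site_id).
    """
    meta = sample_meta.set_index("sample_id")
    missing = [s for s in matrix.values.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    site_of = meta["site_id"]
    rows = []
    for site_id, samples in sorted(
        matrix.values.columns.to_series().groupby(site_of.loc[matrix.values.columns]).groups.items()
    ):
        block = matrix.values[list(samples)]
        means = block.mean(axis=1)
        for motu_id, mean_ab in means.items():
            rows.append(
                {
                    "motu_id": motu_id,
                    "site_id": site_id,
                    "mean_abundance": float(mean_ab),
                    "n_samples": block.shape[1],
                }
            )
    table = pd.DataFrame(rows, columns=["motu_id", "site_id", "mean_abundance", "n_samples"])
    return apply_presence_cutoff(OccupancyTable(table=table, cutoff=cutoff), cutoff)


def apply_presence_cutoff(table: OccupancyTable, cutoff: float = 0.0003) -> OccupancyTable:
    """Set the presence flag: present ⇔ mean abundance ≥ cutoff (inclusive)."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    df = table.table.copy()
    df["present"] = df["mean_abundance"] >= cutoff
    return OccupancyTable(table=df, cutoff=cutoff)


def profile_samples(
    reads_by_sample: Mapping[str, Sequence[tuple[str, str]]],
    genomes: Mapping[str, str],
    genome_to_motu: Mapping[str, str],
    read_length: int = 150,
    subsample: int = 1_000_000,
    seed: int = 0,
    ambiguous: str = "split",
    motu_ids: Sequence[str] | None = None,
) -> AbundanceMatrix:
    """Full per-sample profiling: subsample, match, assign, normalise.

    ``genomes`` must contain only genomes with a mOTU assignment
    (excluded genomes do not compete for reads).  ``motu_ids`` fixes the
    row set of the output matrix (defaults to the mOTUs seen in
    ``genome_to_motu``).
    """
    unknown = sorted(set(genomes) - set(genome_to_motu))
    if unknown:
        raise ValueError(f"genomes without mOTU assignment in the index: {unknown}")
    index = ExactMatchIndex(genomes, read_length=read_length)
    rows = sorted(motu_ids) if motu_ids is not None else sorted(set(genome_to_motu.values()))
    columns = sorted(reads_by_sample)
    values = pd.DataFrame(0.0, index=rows, columns=columns)
    unmapped = pd.Series(0.0, index=columns)
    exact: dict[str, dict[str, Fraction]] = {}
    exact_unmapped: dict[str, Fraction] = {}
    n_sub: dict[str, int] = {}
    for i, sample_id in enumerate(columns):
        sub = subsample_reads(
            reads_by_sample[sample_id], target=subsample, seed=(seed + 7919 * i) & 0x7FFFFFFF
        )
        matches = (index.match(seq) for _, seq in sub)
        counts, unmapped_count = competitive_assign(
            matches, genome_to_motu, ambiguous=ambiguous, seed=seed
        )
        exact[sample_id] = counts
        n = len(sub)
        exact_unmapped[sample_id] = unmapped_count
        n_sub[sample_id] = n
        for motu_id, count in relative_abundance(counts, n).items():
            values.loc[motu_id, sample_id] = count
        unmapped[sample_id] = float(Fraction(unmapped_count) / n)
    return AbundanceMatrix(
        values=values, unmapped=unmapped, subsample_size=subsample, seed=seed,
        exact_counts=exact, exact_unmapped=exact_unmapped, n_subsampled=n_sub,
    )
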