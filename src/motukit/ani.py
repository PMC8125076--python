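"""Average nucleotide identity (ANI) estimation from canonical k-mer sets.

Two genomes of the same species share >95% ANI by convention; this module
estimates ANI from the Jaccard similarity of their canonical k-mer sets
using the MinHash distance transform

    D = -(1/k) * ln(2J / (1 + J)),    ANI = 100 * (1 - D)

with J = |A ∩ B| / |A ∪ B|.  By default the *full* k-mer set of each
genome is used (draft genomes at desk scale are small); a fixed-size
bottom sketch is available for larger inputs.

Pairwise results live in an :class:`ANITable`, which also reads and writes
the five-column FastANI-style TSV dialect
(query, reference, ANI, mapped fragments, total fragments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "sketch_genome",
    "estimate_ani",
    "pairwise_ani",
    "ANITable",
    "read_ani_table",
]

# base -> 2-bit code; anything else (N, gaps) maps to -1 and voids the window
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def canonical_kmer_codes(sequence: str, k: int) -> np.ndarray:
    """All canonical k-mers of ``sequence`` as 2-bit-packed uint64 codes.

    Canonical means the lexicographic minimum of a k-mer and its reverse
    complement, so a sequence and its reverse complement produce the same
    set.  Windows containing non-ACGT symbols are skipped.  Returns the
    *unique sorted* codes (a set, in array form).
    """
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    if len(sequence) < k:
        raise ValueError(f"sequence length {len(sequence)} is shorter than k={k}")
    codes = _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    invalid = codes < 0
    windows = np.lib.stride_tricks.sliding_window_view(np.where(invalid, 0, codes), k)
    # windows touching any invalid base are dropped
    bad = np.lib.stride_tricks.sliding_window_view(invalid, k).any(axis=1)
    weights_fwd = (4 ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    weights_rev = weights_fwd[::-1]
    w = windows.astype(np.uint64)
    fwd = w @ weights_fwd
    rev = (3 - w) @ weights_rev  # reverse complement code
    canon = np.minimum(fwd, rev)[~bad]
    return np.unique(canon)


def sketch_genome(sequence: str, k: int = 21, sketch_size: int | None = None) -> np.ndarray:
    """Canonical k-mer sketch of a genome sequence.

    Parameters
    ----------
    sequence : str
        Nucleotide sequence; non-ACGT symbols void the windows they touch.
    k : int
        Odd k-mer size in [11, 31].  Odd k means no k-mer is its own
        reverse complement, so canonicalisation is unambiguous.
    sketch_size : int, optional
        If given, keep only the ``sketch_size`` smallest canonical codes
        (a bottom sketch).  Default keeps the full set.

    Returns
    -------
    numpy.ndarray
        Sorted unique uint64 k-mer codes.
    """
    if k % 2 == 0 or not 11 <= k <= 31:
        raise ValueError(f"k must be odd and in [11, 31], got {k}")
    codes = canonical_kmer_codes(sequence, k)
    if sketch_size is not None and codes.size > sketch_size:
        codes = codes[:sketch_size]  # already sorted: bottom sketch
    return codes


def estimate_ani(sketch_a: np.ndarray, sketch_b: np.ndarray, k: int = 21) -> float:
    """ANI percent between two sketches via the MinHash distance transform.

    J = 0 (disjoint sketches) is floored to ANI = 0; identical sketches
    give exactly 100.  The estimate is monotone increasing in the Jaccard
    similarity.
    """
    if sketch_a.size == 0 or sketch_b.size == 0:
        raise ValueError("cannot estimate ANI from an empty sketch")
    inter = np.intersect1d(sketch_a, sketch_b, assume_unique=True).size
    union = sketch_a.size + sketch_b.size - inter
    jaccard = inter / union
    if jaccard == 0.0:
        return 0.0
    dist = -math.log(2.0 * jaccard / (1.0 + jaccard)) / k
    return float(min(100.0, max(0.0, 100.0 * (1.0 - dist))))


def pairwise_ani(
    genomes: Mapping[str, str], k: int = 21, sketch_size: int | None = None
) -> "ANITable":
    """All-vs-all ANI over an ``{genome_id: sequence}`` mapping."""
    sketches = {g: sketch_genome(s, k=k, sketch_size=sketch_size) for g, s in genomes.items()}
    table = ANITable(provenance="estimated")
    ids = sorted(sketches)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            table.set(a, b, estimate_ani(sketches[a], sketches[b], k=k))
    return table


@dataclass
class ANITable:
    """Symmetric pairwise ANI percentages over genome ids.

    ``entries`` is keyed by the sorted id pair; self-pairs are implicit
    (100).  ``provenance`` records whether the values were estimated here
    or imported from an external tool's TSV.
    """

    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    provenance: str = "estimated"

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, ani: float) -> None:
        if not 0.0 <= ani <= 100.0:
            raise ValueError(f"ANI must be in [0, 100], got {ani} for ({a}, {b})")
        if a == b:
            return  # self-ANI is implicit
        self.entries[self._key(a, b)] = float(ani)

    def get(self, a: str, b: str, default: float = 0.0) -> float:
        if a == b:
            return 100.0
        return self.entries.get(self._key(a, b), default)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self._key(*pair) in self.entries

    def genome_ids(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.entries:
            out.add(a)
            out.add(b)
        return out

    def write(self, path: str | Path) -> None:
        """Write the five-column TSV dialect (one row per unordered pair)."""
        with open(path, "w") as fh:
            for (a, b), ani in sorted(self.entries.items()):
                fh.write(f"{a}\t{b}\t{ani:.4f}\t0\t0\n")


def read_ani_table(path: str | Path) -> ANITable:
    """Read a five-column (FastANI-style) ANI TSV into an :class:`ANITable`.

    Query and reference fields may be file paths; the basename without
    extension is used as the genome id.  Directed duplicates (A→B and
    B→A) are symmetrised by the arithmetic mean of the two values;
    self-pairs are dropped.  Missing pairs stay absent and are treated as
    below any clustering threshold downstream.
    """
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected ≥3 tab-separated columns")
            a, b = (_strip_path(parts[0]), _strip_path(parts[1]))
            try:
                ani = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: ANI field not numeric: {parts[2]!r}") from exc
            if not 0.0 <= ani <= 100.0:
                raise ValueError(f"{path}: line {lineno}: ANI {ani} outside [0, 100]")
            if a == b:
                continue
            key = ANITable._key(a, b)
            sums[key] = sums.get(key, 0.0) + ani
            counts[key] = counts.get(key, 0) + 1
    table = ANITable(provenance="imported")
    for key, total in sums.items():
        table.entries[key] = total / counts[key]
    return table


def _strip_path(name: str) -> str:
    stem = Path(name).name
    for ext in (".fa", ".fasta", ".fna"):
        if stem.endswith(ext):
            return stem[: -len(ext)]
    return stem
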