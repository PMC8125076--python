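"""FASTA/FASTQ helpers shared across the pipeline.

Thin wrappers around :mod:`Bio.SeqIO` so every module reads and writes
sequences the same way, plus reverse-complement and deterministic
sub-seeding utilities.
"""

from __future__ import annotations

import zlib
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: fixed Phred symbol written for simulated reads (quality is not modelled)
FIXED_QUALITY = "I"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGT alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def stable_label_seed(label: str) -> int:
    """Deterministic 31-bit integer derived from a text label.

    Used to give each species/sample its own reproducible random stream
    from one top-level seed, independent of dict ordering or platform
    hash randomisation.
    """
    return zlib.crc32(label.encode("utf-8")) & 0x7FFFFFFF


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Mapping[str, str]) -> None:
    """Write an ``{id: sequence}`` mapping as FASTA."""
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTQ file into a list of ``(read_id, sequence)`` pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]]) -> None:
    """Write ``(read_id, sequence)`` pairs as FASTQ with a fixed quality."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{FIXED_QUALITY * len(seq)}\n")
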