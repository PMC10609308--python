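"""Sequence records, FASTA I/O and elementary DNA operations.

All pipeline stages exchange :class:`SequenceRecord` lists.  Coordinates
throughout the package are 0-based, half-open, on the forward strand of the
named contig; reverse-strand features carry a strand flag instead of flipped
coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "write_bed",
    "revcomp",
    "gc_percent",
]

_DNA = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (genome contig, region, or template).

    ``seq`` is stored uppercase over the alphabet {A, C, G, T, N}.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (e.g. a header with no sequence)."""


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into a list of :class:`SequenceRecord`.

    Sequences are uppercased (soft-masked lowercase bases are kept) and
    whitespace inside records is stripped by the parser.  Record order is
    preserved.  A header with an empty sequence raises
    :class:`FastaFormatError` naming the offending header.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise FastaFormatError(
                    f"record '{rec.id}' in {path} has an empty sequence"
                )
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id) :].strip()
            records.append(SequenceRecord(rec.id, seq, desc))
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = 60
) -> None:
    """Write records as wrapped FASTA; an empty list yields an empty file."""
    if width <= 0:
        raise ValueError("line width must be positive")
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        for rec in records:
            bio = SeqRecord(Seq(rec.seq), id=rec.id, description=rec.description)
            writer.write_record(bio)


def write_bed(intervals, path: str | Path) -> None:
    """Write (chrom, start, end, name, score, strand) tuples as BED6."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """GC content as a percentage, rounded half-up to two decimals.

    The sequence must be non-empty and N-free (GC of a gapped scaffold
    window is undefined).
    """
    if not seq:
        raise ValueError("gc_percent of an empty sequence is undefined")
    _check_alphabet(seq)
    if "N" in seq:
        raise ValueError("gc_percent is undefined for sequences containing N")
    frac = 100.0 * (seq.count("G") + seq.count("C")) / len(seq)
    # round half-up (Python's round() is banker's rounding)
    return int(frac * 100 + 0.5) / 100.0
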