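"""Sequence I/O and circularity-aware coordinate arithmetic.

All coordinates in this package are 0-based, half-open, on the forward
(reference) strand; strand-specific sequences are derived views. On a
circular genome, window coordinates are taken modulo the genome length, so
an interval's ``end`` may exceed the genome length as the unwrapped image of
a window spanning the origin junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Raised for malformed sequences or out-of-range coordinates."""


@dataclass(frozen=True)
class Genome:
    """A named nucleotide sequence with a circular/linear topology flag."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise SequenceError(f"record {self.name!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise SequenceError(
                f"record {self.name!r}: invalid characters after normalization: "
                f"{sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open forward-strand interval with a strand.

    ``end`` may exceed the genome length only as the unwrapped image of a
    window wrapping the origin of a circular genome.
    """

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise SequenceError(f"empty interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise SequenceError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def positions(self, genome_length: int | None = None):
        """Forward-strand positions covered, modulo length if given."""
        if genome_length is None:
            return range(self.start, self.end)
        return ((p % genome_length) for p in range(self.start, self.end))

    def contains(self, position: int, genome_length: int | None = None) -> bool:
        if genome_length is None:
            return self.start <= position < self.end
        return (position - self.start) % genome_length < self.length


def normalize_sequence(raw: str, name: str = "?") -> str:
    """Uppercase and map U->T; reject anything outside A/C/G/T/N."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - VALID_BASES
    if bad:
        raise SequenceError(
            f"record {name!r}: invalid characters after normalization: {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | Path, circular: bool = True) -> list[Genome]:
    """Read all records of a FASTA file into :class:`Genome` objects.

    Topology is an artifact-level convention, not encoded in FASTA: the
    caller says whether records are circular (the default suits organellar
    references).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return [
        Genome(name=rec.id, sequence=normalize_sequence(str(rec.seq), rec.id), circular=circular)
        for rec in records
    ]


def read_genome(path: str | Path, circular: bool = True) -> Genome:
    """Read the first FASTA record."""
    return read_fasta(path, circular=circular)[0]


def reverse_complement(seq: str) -> str:
    bad = set(seq) - VALID_BASES
    if bad:
        raise SequenceError(f"invalid characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def fetch_window(genome: Genome, start: int, length: int, strand: str = "+") -> str:
    """Window of ``length`` bases read 5'->3' on the requested strand.

    On a circular genome the start index is taken modulo the genome length
    and the window may span the origin junction; on a linear genome any
    out-of-bounds access is an error.
    """
    if length < 1:
        raise SequenceError("window length must be >= 1")
    if length > genome.length:
        raise SequenceError(
            f"window length {length} exceeds genome length {genome.length}"
        )
    if strand not in ("+", "-"):
        raise SequenceError(f"invalid strand {strand!r}")
    L = genome.length
    if genome.circular:
        start %= L
        if start + length <= L:
            window = genome.sequence[start : start + length]
        else:
            window = genome.sequence[start:] + genome.sequence[: start + length - L]
    else:
        if start < 0 or start + length > L:
            raise SequenceError(
                f"window [{start}, {start + length}) out of bounds on linear "
                f"genome of length {L}"
            )
        window = genome.sequence[start : start + length]
    return window if strand == "+" else reverse_complement(window)
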