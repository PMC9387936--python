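"""Genome and interval I/O under fixed coordinate conventions.

All coordinates are 0-based half-open (BED convention). Soft-masked
lowercase letters are preserved on read because the G4 detection pattern
deliberately matches lowercase ``g``; uppercasing would silently change
match counts in repeat-masked regions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "GenomeAssembly",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "extract_sequence",
]

_VALID_STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} is empty or inverted"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class IntervalSet(Sequence[GenomicInterval]):
    """An ordered collection of intervals; order is preserved from input."""

    def __init__(self, intervals: Sequence[GenomicInterval] = ()) -> None:
        self._intervals: tuple[GenomicInterval, ...] = tuple(intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return IntervalSet(self._intervals[i])
        return self._intervals[i]

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals)"

    def lengths(self) -> list[int]:
        """Interval lengths in order; its multiset is what shuffling preserves."""
        return [iv.length for iv in self._intervals]

    def total_length(self) -> int:
        return sum(iv.length for iv in self._intervals)


@dataclass
class GenomeAssembly:
    """Named, ordered chromosome sequences; the coordinate universe.

    Sequences may mix cases (soft-masking); case is preserved.
    """

    records: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # dict preserves insertion order; keys are unique by construction,
        # duplicate detection happens in read_fasta / add_record.
        self.records = dict(self.records)

    def add_record(self, name: str, sequence: str) -> None:
        if name in self.records:
            raise ValueError(f"duplicate chromosome name {name!r}")
        self.records[name] = sequence

    @property
    def chrom_names(self) -> list[str]:
        return list(self.records)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.records.items()}

    def sequence(self, chrom: str) -> str:
        try:
            return self.records[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def total_length(self) -> int:
        return sum(len(s) for s in self.records.values())


def read_fasta(path: str | os.PathLike) -> GenomeAssembly:
    """Read a multi-record FASTA into a :class:`GenomeAssembly`.

    The header text up to the first whitespace becomes the chromosome
    name. Case is preserved. Duplicate names and empty files are errors.
    """
    assembly = GenomeAssembly()
    for record in SeqIO.parse(str(path), "fasta"):
        assembly.add_record(record.id, str(record.seq))
    if not assembly.records:
        raise ValueError(f"no FASTA records found in {path}")
    return assembly


def write_fasta(assembly: GenomeAssembly, path: str | os.PathLike, width: int = 80) -> str:
    """Write the assembly as FASTA with fixed line wrapping; returns path."""
    with open(path, "w") as fh:
        for name, seq in assembly.records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return str(path)


def _parse_bed_line(line: str, lineno: int) -> GenomicInterval:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 3:
        raise ValueError(f"line {lineno}: expected >=3 tab-separated columns")
    chrom = cols[0]
    try:
        start, end = int(cols[1]), int(cols[2])
    except ValueError:
        raise ValueError(f"line {lineno}: non-integer coordinates {cols[1]!r}, {cols[2]!r}")
    if end <= start:
        raise ValueError(f"line {lineno}: end <= start ({start}, {end})")
    name = cols[3] if len(cols) > 3 and cols[3] not in ("", ".") else None
    strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
    return GenomicInterval(chrom, start, end, name=name, strand=strand)


def read_bed(path: str | os.PathLike) -> IntervalSet:
    """Read BED3-BED6 (tab-separated, 0-based half-open) preserving order.

    ``track``/``browser``/``#`` lines and blank lines are skipped; columns
    beyond 6 are ignored (peak callers emit variable extras).
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("track", "browser", "#")):
                continue
            intervals.append(_parse_bed_line(line, lineno))
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path: str | os.PathLike) -> str:
    """Write intervals as BED6; round-trips field-for-field via read_bed."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
    return str(path)


def extract_sequence(genome: GenomeAssembly, interval: GenomicInterval) -> str:
    """Forward-strand substring ``[start, end)`` of the interval's chromosome.

    No strand flipping happens here: strand handling belongs to the
    detectors, which scan both strands themselves.
    """
    try:
        seq = genome.sequence(interval.chrom)
    except KeyError:
        raise ValueError(f"interval {interval} references unknown chromosome") from None
    if interval.end > len(seq):
        raise ValueError(
            f"interval {interval} out of bounds for {interval.chrom} (length {len(seq)})"
        )
    return seq[interval.start : interval.end]
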