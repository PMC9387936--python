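"""AP-1 consensus scanning over peak sequences.

Identifies peaks containing at least one occurrence of an IUPAC consensus
(default ``TGASTCA``, the AP-1/Jun-Fos core) on either strand. This is a
consensus scan, not de novo motif discovery: it stands in for upstream
motif-calling when selecting which peaks enter the G4 analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import reverse_complement

from .genome_io import GenomeAssembly, GenomicInterval, IntervalSet, extract_sequence

__all__ = ["MotifHit", "scan_iupac", "peaks_with_motif", "DEFAULT_CONSENSUS"]

DEFAULT_CONSENSUS = "TGASTCA"

# Each IUPAC code expands to its concrete base set. A literal N in the
# scanned sequence matches only consensus code N (masked gaps must not
# create hits).
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGTN",
}


@dataclass(frozen=True)
class MotifHit:
    """A consensus occurrence; footprint is in forward coordinates."""

    interval: GenomicInterval
    strand: str
    matched_sequence: str


def _consensus_regex(consensus: str) -> re.Pattern:
    parts = []
    for letter in consensus:
        try:
            bases = _IUPAC[letter.upper()]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {letter!r} in consensus") from None
        parts.append("[" + bases + bases.lower() + "]")
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_iupac(sequence: str, consensus: str) -> list[tuple[int, str, str]]:
    """All consensus occurrences on both strands of ``sequence``.

    Returns ``(offset, strand, matched)`` triples with the footprint given
    in forward coordinates. Minus-strand hits are located by scanning the
    reverse complement of the consensus on the forward sequence; their
    ``matched`` text is the sequence as read 5'->3' on the minus strand.
    Hits whose footprints coincide (reverse-palindromic consensus plus a
    palindromic site) collapse to a single plus-strand record.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    fwd = _consensus_regex(consensus)
    rev = _consensus_regex(reverse_complement(consensus))
    plus = {m.start(): m.group(1) for m in fwd.finditer(sequence)}
    hits: list[tuple[int, str, str]] = [(o, "+", s) for o, s in plus.items()]
    for m in rev.finditer(sequence):
        if m.start() in plus:
            continue  # identical footprint already reported on +
        hits.append((m.start(), "-", reverse_complement(m.group(1))))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def find_motif_hits(
    genome: GenomeAssembly, peaks: IntervalSet, consensus: str = DEFAULT_CONSENSUS
) -> list[MotifHit]:
    """Consensus occurrences in every peak, footprints in genome coordinates."""
    out: list[MotifHit] = []
    k = len(consensus)
    for peak in peaks:
        seq = extract_sequence(genome, peak)
        for offset, strand, matched in scan_iupac(seq, consensus):
            footprint = GenomicInterval(
                peak.chrom, peak.start + offset, peak.start + offset + k,
                name=peak.name, strand=strand,
            )
            out.append(MotifHit(footprint, strand, matched))
    return out


def peaks_with_motif(
    genome: GenomeAssembly, peaks: IntervalSet, consensus: str = DEFAULT_CONSENSUS
) -> IntervalSet:
    """Subset of peaks whose sequence contains >=1 consensus occurrence.

    Order is preserved and each peak appears at most once regardless of
    how many occurrences it carries.
    """
    kept = [
        peak
        for peak in peaks
        if scan_iupac(extract_sequence(genome, peak), consensus)
    ]
    return IntervalSet(kept)
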