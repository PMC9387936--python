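"""Scan a small hand-made genome for AP-1 consensus sites and putative
quadruplexes, showing the two detectors on known sequences.

Run:  python examples/scan_peaks_for_ap1_and_g4.py
"""

from g4enrich import (
    GenomeAssembly,
    GenomicInterval,
    IntervalSet,
    count_g4_both_strands,
    peaks_with_motif,
    scan_iupac,
)

# A peak carrying both an AP-1 site (TGACTCA) and a human-telomere-type
# quadruplex (GGGTTA x 4), and a second peak with neither.
telomeric = "GGGTTAGGGTTAGGGTTAGGG"
peak1_seq = "AACC" + "TGACTCA" + "TT" + telomeric + "ACGT"
genome = GenomeAssembly({"chr1": peak1_seq + "ACGTACGTAAACCCTTTGGA" * 2})
peaks = IntervalSet([
    GenomicInterval("chr1", 0, len(peak1_seq), name="peak_with_both"),
    GenomicInterval("chr1", len(peak1_seq), len(peak1_seq) + 40, name="empty_peak"),
])

hits = scan_iupac(peak1_seq, "TGASTCA")
print(f"AP-1 consensus hits in peak 1: {hits}")
print("  (offset, strand, matched) — S accepts C or G; the reverse-")
print("  palindromic footprint collapses to one plus-strand record")

selected = peaks_with_motif(genome, peaks, "TGASTCA")
print(f"peaks passing the motif filter: {[p.name for p in selected]}")

fwd, rev, _ = count_g4_both_strands(peak1_seq)
print(f"G4 matches in peak 1: {fwd} forward, {rev} reverse strand")
fwd_c, rev_c, _ = count_g4_both_strands(peak1_seq.replace(telomeric, ""))
print(f"after removing the telomeric repeat: {fwd_c} forward, {rev_c} reverse")
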