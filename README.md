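# g4enrich

Permutation-based enrichment analysis of putative G-quadruplex-forming
sequences (PQS) in regulatory genomic intervals, plus the qPCR
quantification arithmetic that usually accompanies such studies.

## Who this is for

Chromatin and gene-regulation researchers who have a set of peaks —
ATAC-seq open-chromatin regions, transcription-factor binding sites,
promoter windows — and want to know whether quadruplex-forming sequence
is over-represented in them relative to random placement on the same
genome. The package also covers the bench-side arithmetic of the same
projects: 2^−ΔΔCq relative expression, ChIP-qPCR percent input and fold
enrichment over a negative-control locus.

## The method

**G4 detection.** A PQS is at least four runs of ≥3 guanines separated
by loops of 1–12 characters, matched with the pattern

```
([gG]{3,}\w{1,12}){3,}[gG]{3,}
```

under leftmost-first, greedy, non-overlapping semantics, on the forward
sequence and on its reverse complement (C-rich template strands).
Lowercase `g` matches so soft-masked repeats participate.

**Enrichment.** With observed count *O* (total PQS matches in the
peaks) and a null built by re-placing the peak set uniformly at random
on the genome *R* times — preserving peak number and the multiset of
peak lengths — the report gives

- percent excess: 100 · (*O* − mean(null)) / mean(null),
- empirical p: (*b* + 1)/(*R* + 1) with *b* = number of permutations
  reaching ≥ *O* (one-sided, add-one, so never 0), and
- the fraction of peaks containing ≥1 PQS.

As a worked check on published numbers: 63 observed G4s against a null
mean of 43 gives 100·20/43 = 46.5%, i.e. “47% more than expected” at
integer rounding.

**AP-1 selection.** Peaks can first be filtered to those containing an
IUPAC consensus occurrence on either strand (default `TGASTCA`, the
AP-1/Jun–Fos core), standing in for upstream motif calling.

**Synthetic fixtures.** Because a genome-scale dataset is impractical
for testing, `synthetic_data` generates multi-chromosome genomes with
controllable GC, disjoint peaks, planted consensus sites, and planted
quadruplexes at independent densities inside and outside peaks, with a
complete ground-truth manifest.

## Worked example

`python examples/simulate_and_measure_enrichment.py` plants
quadruplexes at 5× higher density inside 200 peaks (400 bp each) than
in the background of a 1-Mb genome, then measures the enrichment:

```
genome: 4 chromosomes, 1,000,000 bp
planted G4s: 31 in peaks, 86 background
detector: 31 G4 matches in 200 peaks (28 peaks G4-positive)
null mean over 100 permutations: 9.3
percent excess: 234.8%  (observed vs. random placement of the same peaks)
empirical p: 0.0099  (1/101 is the smallest attainable at R=100)
```

The detector recovers exactly the 31 planted in-peak quadruplexes (the
40% GC background yields no spontaneous matches at this scale); random
re-placement of the peaks catches planted elements roughly in
proportion to the peak footprint (≈9 of 117), so the observed count
sits far above the null and the empirical p is at its floor of 1/101.

The other examples show the two sequence scanners on hand-made peaks
(`scan_peaks_for_ap1_and_g4.py`) and the qPCR arithmetic
(`qpcr_fold_change.py`), e.g. recovering a simulated 63%-knockdown and
computing 2.6-fold ChIP enrichment over a negative-control locus.

## Command line

The same workflow is scriptable:

```bash
g4enrich simulate --outdir sim --seed 7
g4enrich run --genome sim/genome.fa --peaks sim/peaks.bed \
    --outdir out -R 100 --seed 7          # motif filter + G4 + null + stats
g4enrich run ... --skip-motif-filter      # peak list already motif-selected
g4enrich qpcr --cq-table cq.tsv --target IFNB1 --housekeeping GAPDH \
    --sample treated --calibrator control
```

`run` writes the motif-positive peak BED, per-peak G4 hit and summary
TSVs, the null counts and histogram tables, a JSON result record and a
log with the seed and configuration echo.

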