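# Methods

## Quadruplex detection

A putative quadruplex-forming sequence (PQS) is defined purely at the
sequence level: four or more tracts of at least three guanines
separated by loops of 1–12 characters, i.e. the regular expression
`([gG]{3,}\w{1,12}){3,}[gG]{3,}`. Matching semantics are part of the
contract, not an implementation detail: scanning is leftmost-first
with greedy quantifiers and span consumption (standard `finditer`
behaviour), so when a G-rich region could be decomposed in several
ways the greedy leftmost decomposition decides the count. The test
suite pins this with a hand-written recursive backtracking matcher
that simulates exactly that preference order and is checked for exact
agreement on tens of thousands of fuzzed strings, including
adversarially G-dense ones.

Consequences of the pattern worth knowing:

- Lowercase `g` matches, so soft-masked (repeat) sequence participates
  in detection deliberately; uppercasing a sequence never changes the
  match count.
- Loop positions accept any word character. `N` can therefore sit in a
  loop but never in a G-tract, and long `N` gaps (≥13) break a PQS.
- The reverse strand is searched by applying the same pattern to the
  reverse complement; coordinates map back via start′ = len − end. A
  G-rich forward match and a C-rich reverse match can never be the
  same subsequence, so per-strand counts are summed without
  deduplication. Forward and reverse matches *can* overlap in genome
  space for interleaved G/C runs; both are counted.
- No thermodynamics, no scoring, no two-tract or imperfect
  quadruplexes: this is a pattern census, not a stability prediction.

The observed statistic of an analysis is the **total number of
matches** across peaks; the **fraction of peaks with ≥1 match** is
reported separately because it answers a different question (breadth
rather than density of quadruplex potential).

## Permutation null and enrichment statistics

The null hypothesis is "the peak set is placed at random on this
genome". Each of R permutations re-places every peak independently:
a chromosome is chosen with probability proportional to its number of
valid start positions for that peak's length (L − ℓ + 1), then a start
is drawn uniformly. This weighting — rather than raw chromosome length
— makes placement exactly uniform over all valid genomic positions
even when peaks are long relative to the smallest chromosome. Placed
peaks may overlap one another and no exclusion regions (gaps,
blacklists) are applied; on real genomes with large assembly gaps this
will make the absolute null mean somewhat conservative, which is a
known divergence from nulls that exclude gaps. Peak number and the
length multiset are preserved by construction; chromosome-of-origin is
not, since the null is genome-wide placement.

Per-permutation random streams derive from `(master seed, permutation
index)` via `numpy.random.SeedSequence` spawn keys, so the null is
bit-identical across runs and platforms for a fixed seed and
permutations are mutually independent.

Reported statistics:

- **percent excess** = 100 (O − mean(null)) / mean(null); undefined
  (an error) when the null mean is ≤ 0. Displayed at one decimal;
  integer display rounds half away from zero.
- **empirical p** = (b + 1)/(R + 1), b = #{null counts ≥ O}. One-sided
  (enrichment), add-one so the smallest attainable value at R = 100 is
  1/101 ≈ 0.0099. No parametric model of counts is fitted.

A subtlety the tests account for: observed planted elements lie wholly
inside peaks, whereas a randomly placed window only counts an element
it fully contains. The expected null contribution of an element of
inner length ℓ in a window of width W is therefore proportional to
W − ℓ + 1, not W, and the expected percent excess at planted
peak-vs-background density ratio ρ follows from that containment
model, not from the naive 100(ρ − 1) (which additionally ignores the
peaks' own contribution to the genome-average density). The
parameter-recovery test asserts the containment-model expectation
within three standard errors over seeded replicates.

## AP-1 consensus scanning

Motif selection is a case-insensitive IUPAC consensus scan (default
`TGASTCA`) at every offset on both strands, with minus-strand hits
reported as forward-coordinate footprints and reverse-palindromic
double hits collapsed to a single plus-strand record. Overlapping
occurrences are all reported (no consumption — a fixed-length window
scan). A literal `N` in the scanned sequence matches only consensus
code `N`, so masked stretches cannot create hits. This replaces de
novo motif discovery by design: the analysis assumes the consensus is
known, and the consensus is overridable wherever it appears.

## qPCR arithmetic

- **2^−ΔΔCq**: ΔCq = mean(target Cq) − mean(housekeeping Cq) within a
  condition, using replicate means rather than per-replicate pairing
  (the convention when results are reported as triplicate means ± SD);
  ΔΔCq = ΔCq(sample) − ΔCq(calibrator); relative expression is
  2^−ΔΔCq. Amplification efficiency is fixed at 2 — no standard-curve
  correction is implemented.
- **Percent input** (ChIP) = 100 · input_fraction · 2^(Cq_input − Cq_IP).
  The input dilution fraction is kit-defined and must be supplied; it
  is not inferable from Cq values. The statistic is invariant to
  adding a constant to both Cq values.
- **Fold over reference**: percent-input ratio against a
  negative-control locus (reference set to 1).
- **t-test on ΔCq values**: classical pooled-variance (Student)
  two-sample test, two-tailed, n_a + n_b − 2 degrees of freedom,
  computed via `scipy.stats.ttest_ind(equal_var=True)` and pinned
  against an independently coded textbook-formula evaluation in the
  tests. Pooled variance (not Welch) is the deliberate choice, and no
  multiple-testing correction is applied.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes
— quadruplexes concentrated in motif-bearing open-chromatin peaks —
not real chromatin. Defaults: 4 chromosomes × 250 kb, 40% GC, 200
disjoint peaks of 400 bp (an 8% footprint), half the peaks receiving
one planted AP-1 consensus (`TGACTCA`, random strand), planted
quadruplex rates of 0.2 per peak and 0.04 per 400 bp of background
(a 5× density ratio). These sizes keep a full pipeline run with R=100
permutations around a second while leaving ≈30–40 planted in-peak
elements, enough for the permutation test to saturate at p = 1/101.

Planted quadruplexes are sampled as four G-tracts of length 3–5 joined
by three loops of 1–7 non-G letters — guaranteed pattern matches — and
inserted by substitution between 13-bp A/T-only spacers. Since loops
are ≤12 characters and the spacers contain neither G nor C, a planted
element can neither merge with neighbouring G-runs nor be extended by
the greedy matcher on either strand, so the detector recovers every
planted quadruplex at exactly its recorded location and strand; the
truth manifest is exact, not approximate. Planted elements never
overlap each other or planted motifs (rejection sampling with reserved
blocks). Minus-strand plants substitute the reverse complement.
`g4_rate_background` is interpreted per mean-peak-length window of
non-peak sequence, so equal peak and background rates mean equal
planted density.

What the generator does **not** emulate: repeat structure and
CpG islands, chromatin-biology correlations between motifs and
accessibility, read-level noise, assembly gaps, and the spontaneous
PQS density of a real 40–60% GC genome (at the default 40% GC and 1 Mb
the spontaneous match count is ~0, which is what makes exact
planted-truth accounting possible). Passing tests therefore certify
the detection, placement and arithmetic machinery — not that any
particular real peak set is enriched.

The qPCR generator draws housekeeping Cq around 20 and target Cq
around 25 (calibrator), shifts the treated target by −log2(fold
change), and adds Gaussian per-replicate noise. With noise, 2^−ΔΔCq is
lognormal, so the mean recovered fold sits slightly above the true
fold by the analytic factor exp((ln2 · σ_ΔΔCq)²/2); the Monte-Carlo
recovery test asserts against that analytic mean.

## Numerical and interface choices

- Coordinates are 0-based half-open everywhere (BED convention);
  1-based numbers appear only in formatted output.
- BED columns beyond 6 are ignored; `track`/`browser`/`#` lines are
  skipped; strand defaults to `.` (peak strand is irrelevant to both
  scanners, which always search both strands).
- FASTA I/O goes through Biopython; header text up to the first
  whitespace is the chromosome name; case is preserved.
- All randomness flows through `numpy.random.default_rng`; every
  public entry point takes an explicit seed and logs it.
- Empty peak sets, zero-length intervals, out-of-bounds intervals,
  duplicate chromosome names, non-positive null means, and sub-minimal
  replicate counts are hard errors with the offending record named,
  never silent coercions.

## Known limitations

- The permutation null ignores GC content, repeats and assembly gaps;
  on real genomes the enrichment against this null conflates
  quadruplex enrichment with plain GC enrichment of open chromatin.
  A GC- or repeat-matched null is out of scope.
- The pattern census treats all loops 1–12 equally and requires
  perfect tracts; scoring-based predictors will disagree at the
  margins.
- Whether overlapping forward/reverse matches should both count is a
  judgment call; both are counted here and flagged as such.
- The CLI `enrich`/`run` workflow holds the genome in memory; it is
  sized for desk-scale genomes (tens of Mb), not mammalian assemblies.
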