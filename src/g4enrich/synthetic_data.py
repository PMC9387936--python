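"""Synthetic genomes, peak sets and qPCR datasets with known ground truth.

The generator emulates the statistical structure the enrichment
analysis assumes: a small multi-chromosome genome with controllable GC
content, non-overlapping open-chromatin peaks, AP-1 consensus sites
planted in a subset of peaks, and quadruplex-forming sequences planted
at a higher density inside peaks than in the background. Every planted
element is recorded in a truth manifest so each pipeline stage can be
checked against what was actually inserted.

Planted quadruplexes are sampled as four G-tracts of length 3-5 joined
by loops of 1-7 non-G letters (guaranteed pattern matches) and are
embedded between 13-bp A/T-only spacers. Because loops are at most 12
characters and the spacers contain no G or C, a planted element can
neither merge with a neighbouring G-run nor be extended by the greedy
matcher, so the detector recovers every planted quadruplex exactly at
its planted location and strand.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from Bio.Seq import reverse_complement

from .genome_io import (
    GenomeAssembly,
    GenomicInterval,
    IntervalSet,
    write_bed,
    write_fasta,
)
from .qpcr_quant import QpcrMeasurement

__all__ = [
    "SimulationConfig",
    "TruthManifest",
    "generate_synthetic_genome",
    "generate_qpcr_dataset",
    "save_simulation",
]

AP1_CONSENSUS_SITE = "TGACTCA"  # a concrete realisation of the TGASTCA consensus
_SPACER = 13  # flank width; > max loop length, so planted G4s are isolated


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic fixture.

    Defaults give a 1-Mb genome (4 x 250 kb) at 40% GC with 200 peaks of
    400 bp — small enough for sub-minute full-pipeline runs while leaving
    the peak footprint a small fraction (8%) of the genome.

    ``g4_rate_peaks`` is the expected number of planted quadruplexes per
    peak; ``g4_rate_background`` is the expected number per mean-peak-length
    window of non-peak sequence, so equal rates mean equal planted density
    and the ratio of the two is the planted peak-vs-background density
    ratio.
    """

    n_chroms: int = 4
    chrom_length: int = 250_000
    gc_content: float = 0.40
    n_peaks: int = 200
    peak_length: int | tuple[int, int] = 400
    motif_rate: float = 0.5
    g4_rate_peaks: float = 0.2
    g4_rate_background: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if not 0 <= self.motif_rate <= 1:
            raise ValueError("motif_rate must be in [0, 1]")
        if self.g4_rate_peaks < 0 or self.g4_rate_background < 0:
            raise ValueError("planting rates must be non-negative")
        if self.n_chroms < 1 or self.chrom_length < 1 or self.n_peaks < 0:
            raise ValueError("genome/peak dimensions must be positive")

    @property
    def mean_peak_length(self) -> float:
        if isinstance(self.peak_length, tuple):
            lo, hi = self.peak_length
            return (lo + hi) / 2
        return float(self.peak_length)

    def draw_peak_length(self, rng: np.random.Generator) -> int:
        if isinstance(self.peak_length, tuple):
            lo, hi = self.peak_length
            return int(rng.integers(lo, hi + 1))
        return int(self.peak_length)


@dataclass
class TruthManifest:
    """What was planted where; the ground truth for recovery tests."""

    planted_motifs: list[GenomicInterval] = field(default_factory=list)
    planted_g4s: list[GenomicInterval] = field(default_factory=list)
    config: SimulationConfig | None = None

    @property
    def n_g4_in_peaks(self) -> int:
        return sum(1 for iv in self.planted_g4s if iv.name == "peak")

    @property
    def n_g4_background(self) -> int:
        return sum(1 for iv in self.planted_g4s if iv.name == "background")

    def to_dict(self) -> dict:
        def _iv(iv: GenomicInterval) -> dict:
            return {
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "compartment": iv.name, "strand": iv.strand,
            }

        cfg = asdict(self.config) if self.config is not None else None
        if cfg is not None and isinstance(cfg.get("peak_length"), tuple):
            cfg["peak_length"] = list(cfg["peak_length"])
        return {
            "planted_motifs": [_iv(iv) for iv in self.planted_motifs],
            "planted_g4s": [_iv(iv) for iv in self.planted_g4s],
            "config": cfg,
        }


class _Occupancy:
    """Per-chromosome list of reserved [start, end) blocks."""

    def __init__(self) -> None:
        self._blocks: dict[str, list[tuple[int, int]]] = {}

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self._blocks.get(chrom, ()))

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self._blocks.setdefault(chrom, []).append((start, end))


def _random_sequences(config: SimulationConfig, rng: np.random.Generator) -> list[bytearray]:
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [
        bytearray(rng.choice(bases, size=config.chrom_length, p=probs).tobytes())
        for _ in range(config.n_chroms)
    ]


def _place_peaks(
    config: SimulationConfig, rng: np.random.Generator
) -> list[GenomicInterval]:
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    lengths = [config.draw_peak_length(rng) for _ in range(config.n_peaks)]
    if sum(lengths) >= 0.5 * config.n_chroms * config.chrom_length:
        raise ValueError("total peak footprint must stay below 50% of the genome")
    occupied = _Occupancy()
    placed: list[GenomicInterval] = []
    for length in lengths:
        if length > config.chrom_length:
            raise ValueError(f"peak length {length} exceeds chromosome length")
        for _ in range(1000):
            chrom = chrom_names[int(rng.integers(0, config.n_chroms))]
            start = int(rng.integers(0, config.chrom_length - length + 1))
            if not occupied.overlaps(chrom, start, start + length):
                occupied.reserve(chrom, start, start + length)
                placed.append(GenomicInterval(chrom, start, start + length))
                break
        else:
            raise ValueError("infeasible packing: could not place peaks disjointly")
    placed.sort(key=lambda iv: (iv.chrom, iv.start))
    return [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=f"peak_{i + 1:04d}")
        for i, iv in enumerate(placed)
    ]


def _sample_g4_sequence(rng: np.random.Generator) -> str:
    tracts = ["G" * int(rng.integers(3, 6)) for _ in range(4)]
    loops = [
        "".join(rng.choice(list("ACT"), size=int(rng.integers(1, 8))))
        for _ in range(3)
    ]
    return tracts[0] + loops[0] + tracts[1] + loops[1] + tracts[2] + loops[2] + tracts[3]


def _spacer(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("AT"), size=_SPACER))


def _substitute(seq: bytearray, start: int, text: str) -> None:
    seq[start : start + len(text)] = text.encode("ascii")


def _plant_block(
    seq: bytearray,
    chrom: str,
    lo: int,
    hi: int,
    inner: str,
    strand: str,
    compartment: str,
    occupied: _Occupancy,
    rng: np.random.Generator,
    pad: int = _SPACER,
) -> GenomicInterval | None:
    """Insert spacer+inner+spacer uniformly inside [lo, hi); returns the
    inner footprint, or None if no non-overlapping position was found."""
    block_len = len(inner) + 2 * pad
    if hi - lo < block_len:
        return None
    for _ in range(200):
        start = int(rng.integers(lo, hi - block_len + 1))
        if not occupied.overlaps(chrom, start, start + block_len):
            planted = inner if strand == "+" else reverse_complement(inner)
            if pad:
                planted = _spacer(rng) + planted + _spacer(rng)
            _substitute(seq, start, planted)
            occupied.reserve(chrom, start, start + block_len)
            return GenomicInterval(
                chrom, start + pad, start + pad + len(inner),
                name=compartment, strand=strand,
            )
    return None


def generate_synthetic_genome(
    config: SimulationConfig | None = None,
) -> tuple[GenomeAssembly, IntervalSet, TruthManifest]:
    """Generate (genome, peaks, truth manifest) for one simulation.

    Background bases are i.i.d. at the configured GC; peaks are placed
    disjointly; motifs and quadruplexes are inserted by substitution and
    never overlap one another. Byte-identical output for a fixed seed.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    sequences = dict(zip(chrom_names, _random_sequences(config, rng)))
    peaks = _place_peaks(config, rng)
    manifest = TruthManifest(config=config)
    occupied = _Occupancy()  # planted blocks only; peaks may contain blocks

    # AP-1 consensus sites in a deterministic fraction of peaks
    n_motif_peaks = round(config.motif_rate * config.n_peaks)
    motif_peak_idx = sorted(
        rng.choice(config.n_peaks, size=n_motif_peaks, replace=False).tolist()
    )
    for i in motif_peak_idx:
        peak = peaks[i]
        strand = "+" if rng.random() < 0.5 else "-"
        iv = _plant_block(
            sequences[peak.chrom], peak.chrom, peak.start, peak.end,
            AP1_CONSENSUS_SITE, strand, "motif", occupied, rng, pad=0,
        )
        if iv is not None:
            manifest.planted_motifs.append(iv)

    # quadruplexes inside peaks
    for peak in peaks:
        for _ in range(int(rng.poisson(config.g4_rate_peaks))):
            iv = _plant_block(
                sequences[peak.chrom], peak.chrom, peak.start, peak.end,
                _sample_g4_sequence(rng), "+" if rng.random() < 0.5 else "-",
                "peak", occupied, rng,
            )
            if iv is not None:
                manifest.planted_g4s.append(iv)

    # quadruplexes in the background (outside every peak)
    peak_blocks = _Occupancy()
    for peak in peaks:
        peak_blocks.reserve(peak.chrom, peak.start, peak.end)
    background_bp = config.n_chroms * config.chrom_length - sum(
        p.length for p in peaks
    )
    n_background = int(
        rng.poisson(config.g4_rate_background * background_bp / config.mean_peak_length)
    )
    placed_bg = 0
    attempts = 0
    while placed_bg < n_background and attempts < 50 * max(n_background, 1):
        attempts += 1
        inner = _sample_g4_sequence(rng)
        block_len = len(inner) + 2 * _SPACER
        chrom = chrom_names[int(rng.integers(0, config.n_chroms))]
        start = int(rng.integers(0, config.chrom_length - block_len + 1))
        if peak_blocks.overlaps(chrom, start, start + block_len):
            continue
        if occupied.overlaps(chrom, start, start + block_len):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        planted = inner if strand == "+" else reverse_complement(inner)
        _substitute(sequences[chrom], start, _spacer(rng) + planted + _spacer(rng))
        occupied.reserve(chrom, start, start + block_len)
        manifest.planted_g4s.append(
            GenomicInterval(chrom, start + _SPACER, start + _SPACER + len(inner),
                            name="background", strand=strand)
        )
        placed_bg += 1

    assembly = GenomeAssembly(
        {name: seq.decode("ascii") for name, seq in sequences.items()}
    )
    return assembly, IntervalSet(peaks), manifest


def generate_qpcr_dataset(
    n_replicates: int = 3,
    true_fold_change: float = 1.0,
    cq_noise_sd: float = 0.1,
    seed: int = 0,
) -> list[QpcrMeasurement]:
    """Replicate Cq values for target and housekeeping genes under a
    calibrator and a treated condition with a known fold change.

    Housekeeping Cq centres on 20 in both conditions, the target on 25
    in the calibrator, and the treated target is shifted by
    -log2(fold change); Gaussian noise of the given SD is added per
    replicate. Deterministic given the seed.
    """
    if n_replicates < 2:
        raise ValueError("need >=2 replicates")
    if true_fold_change <= 0:
        raise ValueError("true_fold_change must be positive")
    if cq_noise_sd < 0:
        raise ValueError("cq_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)

    def draw(mean: float) -> tuple[float, ...]:
        return tuple(float(mean + rng.normal(0, cq_noise_sd)) if cq_noise_sd > 0
                     else float(mean) for _ in range(n_replicates))

    shift = -float(np.log2(true_fold_change))
    return [
        QpcrMeasurement("calibrator", "housekeeping", draw(20.0)),
        QpcrMeasurement("calibrator", "target", draw(25.0)),
        QpcrMeasurement("treated", "housekeeping", draw(20.0)),
        QpcrMeasurement("treated", "target", draw(25.0 + shift)),
    ]


def save_simulation(
    assembly: GenomeAssembly,
    peaks: IntervalSet,
    manifest: TruthManifest,
    outdir: str | os.PathLike,
) -> dict[str, str]:
    """Write genome.fa, peaks.bed and truth.json; returns their paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "peaks": os.path.join(outdir, "peaks.bed"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_fasta(assembly, paths["genome"])
    write_bed(peaks, paths["peaks"])
    with open(paths["truth"], "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2)
    return paths
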