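"""End-to-end orchestration: motif filter -> G4 summary -> null -> enrichment.

Mirrors the command-line workflow: extract sequences for the peaks that
carry the AP-1 consensus, count quadruplex matches on both strands,
build the length-preserving permutation null, and report enrichment.
The motif filter can be skipped so the G4 analysis runs directly on an
externally supplied peak list (e.g. peaks already selected for a motif
by an upstream tool).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass

import pandas as pd

from . import __version__
from .enrichment import EnrichmentResult, plot_null_histogram, summarize_enrichment
from .g4_detect import G4Hit, PeakG4Summary, summarize_peaks
from .genome_io import IntervalSet, read_bed, read_fasta, write_bed
from .motif_scan import DEFAULT_CONSENSUS, peaks_with_motif
from .shuffle_null import build_null_distribution

logger = logging.getLogger("g4enrich")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    genome_path: str
    peaks_path: str
    output_dir: str
    consensus: str = DEFAULT_CONSENSUS
    n_permutations: int = 100
    seed: int = 0
    skip_motif_filter: bool = False
    make_plot: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def _write_hits_tsv(hits: list[G4Hit], peaks: IntervalSet, path: str) -> None:
    by_name = {p.name: p for p in peaks if p.name is not None}
    rows = []
    for h in hits:
        peak = by_name.get(h.peak_name)
        rows.append({
            "peak": h.peak_name,
            "chrom": peak.chrom if peak else "",
            "start": peak.start + h.offset_start if peak else h.offset_start,
            "end": peak.start + h.offset_end if peak else h.offset_end,
            "strand": h.strand,
            "matched_sequence": h.matched_sequence,
        })
    pd.DataFrame(rows, columns=["peak", "chrom", "start", "end", "strand",
                                "matched_sequence"]).to_csv(path, sep="\t", index=False)


def _write_summary_tsv(summaries: list[PeakG4Summary], path: str) -> None:
    pd.DataFrame(
        [{
            "peak": s.peak.name or str(s.peak),
            "chrom": s.peak.chrom, "start": s.peak.start, "end": s.peak.end,
            "count_forward": s.count_forward, "count_reverse": s.count_reverse,
            "count_total": s.count_total, "has_g4": s.has_g4,
        } for s in summaries]
    ).to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> EnrichmentResult:
    """Run the full analysis and write its artifacts to ``output_dir``.

    Writes the motif-positive peak BED (unless the filter is skipped),
    per-peak G4 hit and summary TSVs, the null counts TSV, the null
    histogram table, and a JSON result record echoing the configuration.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    log_path = os.path.join(config.output_dir, "run.log")
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("g4enrich %s; config: %s", __version__, dataclasses.asdict(config))
        genome = read_fasta(config.genome_path)
        peaks = read_bed(config.peaks_path)
        logger.info("loaded %d chromosomes, %d peaks", len(genome.records), len(peaks))
        if not len(peaks):
            raise ValueError("peak file contains no intervals")

        if config.skip_motif_filter:
            selected = peaks
        else:
            selected = peaks_with_motif(genome, peaks, config.consensus)
            write_bed(selected, os.path.join(config.output_dir, "motif_peaks.bed"))
            logger.info("motif filter (%s): %d of %d peaks retained",
                        config.consensus, len(selected), len(peaks))
            if not len(selected):
                raise ValueError(
                    f"motif filter removed every peak (consensus {config.consensus})"
                )

        summaries, hits = summarize_peaks(genome, selected)
        _write_hits_tsv(hits, selected, os.path.join(config.output_dir, "g4_hits.tsv"))
        _write_summary_tsv(summaries, os.path.join(config.output_dir, "g4_summary.tsv"))

        null = build_null_distribution(
            genome, selected, n_permutations=config.n_permutations, seed=config.seed
        )
        pd.DataFrame({
            "permutation_index": range(null.n_permutations),
            "g4_count": null.counts,
        }).to_csv(os.path.join(config.output_dir, "null_counts.tsv"),
                  sep="\t", index=False)

        result = summarize_enrichment(summaries, null)
        hist = result.null_histogram()
        pd.DataFrame({"g4_count": list(hist), "frequency": list(hist.values())}).to_csv(
            os.path.join(config.output_dir, "null_histogram.tsv"), sep="\t", index=False
        )
        if config.make_plot:
            plot_null_histogram(
                result, os.path.join(config.output_dir, "null_histogram.png")
            )

        record = {
            "result": result.to_dict(),
            "config": dataclasses.asdict(config),
            "version": __version__,
        }
        with open(os.path.join(config.output_dir, "result.json"), "w") as fh:
            json.dump(record, fh, indent=2)
        logger.info(
            "observed %d G4s vs null mean %.1f: %.1f%% excess, empirical p %.4g",
            result.observed_count, result.null_mean,
            result.percent_excess, result.empirical_p,
        )
        return result
    finally:
        logger.removeHandler(handler)
        handler.close()
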