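"""Enrichment statistics: observed vs. permutation null.

The headline statistic is *percent excess*, 100 x (observed - null
mean) / null mean — "x% more G4 sequences than expected by chance". The
significance measure is the one-sided add-one empirical p-value
(b + 1) / (R + 1), which is never zero at finite permutation number R.
The fraction of peaks carrying at least one G4 is reported alongside,
as it answers a different question than the match total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections import Counter

from .g4_detect import PeakG4Summary, total_g4_count
from .shuffle_null import NullDistribution

__all__ = [
    "EnrichmentResult",
    "percent_excess",
    "empirical_p_value",
    "summarize_enrichment",
    "round_half_away",
]


def percent_excess(observed: float, null_mean: float) -> float:
    """100 x (observed - null_mean) / null_mean; requires null_mean > 0."""
    if null_mean <= 0:
        raise ValueError("percent excess undefined for non-positive null mean")
    return 100.0 * (observed - null_mean) / null_mean


def empirical_p_value(observed: float, null: NullDistribution) -> float:
    """One-sided (enrichment) add-one permutation p-value.

    (b + 1) / (R + 1) with b = number of null counts >= observed. Bounded
    below by 1/(R + 1): finite permutations cannot certify p = 0.
    """
    b = sum(1 for c in null.counts if c >= observed)
    return (b + 1) / (null.n_permutations + 1)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (display only)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class EnrichmentResult:
    observed_count: int
    null: NullDistribution
    n_peaks: int
    n_peaks_with_g4: int
    null_mean: float = field(init=False)
    null_sd: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "null_mean", self.null.mean)
        object.__setattr__(self, "null_sd", self.null.sd)

    @property
    def percent_excess(self) -> float:
        return percent_excess(self.observed_count, self.null_mean)

    @property
    def empirical_p(self) -> float:
        return empirical_p_value(self.observed_count, self.null)

    @property
    def fraction_peaks_with_g4(self) -> float:
        return self.n_peaks_with_g4 / self.n_peaks

    def null_histogram(self) -> dict[int, int]:
        """Null count value -> frequency; the table behind the histogram."""
        return dict(sorted(Counter(self.null.counts).items()))

    def to_dict(self) -> dict:
        return {
            "observed_count": self.observed_count,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "n_permutations": self.null.n_permutations,
            "percent_excess": round(self.percent_excess, 1),
            "percent_excess_integer": round_half_away(self.percent_excess),
            "empirical_p": self.empirical_p,
            "n_peaks": self.n_peaks,
            "n_peaks_with_g4": self.n_peaks_with_g4,
            "fraction_peaks_with_g4": self.fraction_peaks_with_g4,
            "seed": self.null.seed,
        }


def summarize_enrichment(
    summaries: list[PeakG4Summary], null: NullDistribution
) -> EnrichmentResult:
    """Bundle observed statistics with the null into an EnrichmentResult."""
    if not summaries:
        raise ValueError("need at least one peak summary")
    return EnrichmentResult(
        observed_count=total_g4_count(summaries),
        null=null,
        n_peaks=len(summaries),
        n_peaks_with_g4=sum(1 for s in summaries if s.has_g4),
    )


def plot_null_histogram(result: EnrichmentResult, path: str) -> str:
    """Null-count histogram with the observed count as a vertical line
    and the null mean as a dashed line; writes an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    counts = result.null.counts
    ax.hist(counts, bins="auto", color="0.7", edgecolor="0.4")
    ax.axvline(result.observed_count, color="k", lw=2, label=f"observed ({result.observed_count})")
    ax.axvline(result.null_mean, color="k", ls="--", lw=1.5,
               label=f"null mean ({result.null_mean:.1f})")
    ax.axvspan(result.null_mean - result.null_sd, result.null_mean + result.null_sd,
               color="0.9", zorder=0)
    ax.set_xlabel("G4 matches per permutation")
    ax.set_ylabel("permutations")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
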