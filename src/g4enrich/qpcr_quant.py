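"""qPCR quantification arithmetic.

Relative expression by the 2^-ddCq method (target normalised to a
housekeeping gene and a calibrator condition, assuming a doubling per
cycle), ChIP-qPCR recovery as percent of input chromatin, fold
enrichment over a negative-control locus, and the two-sample Student
t-test applied to per-condition dCq values. dCq uses replicate means;
amplification efficiency is fixed at 2 (no efficiency correction).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = [
    "QpcrMeasurement",
    "ChipMeasurement",
    "delta_cq",
    "relative_expression_ddcq",
    "percent_input",
    "fold_over_reference",
    "t_test_delta_cq",
    "read_cq_table",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    """Replicate quantification cycles for one (sample, gene) pair."""

    sample: str
    gene: str
    cq_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.cq_values:
            raise ValueError(f"{self.sample}/{self.gene}: needs >=1 Cq replicate")
        if any(not math.isfinite(c) or c <= 0 for c in self.cq_values):
            raise ValueError(f"{self.sample}/{self.gene}: Cq values must be finite and positive")

    @property
    def mean_cq(self) -> float:
        return sum(self.cq_values) / len(self.cq_values)


@dataclass(frozen=True)
class ChipMeasurement:
    """One immunoprecipitation qPCR pair: IP Cq, input-aliquot Cq, and
    the fraction of total chromatin the input aliquot represents."""

    antibody: str
    locus: str
    cq_ip: float
    cq_input: float
    input_fraction: float

    def __post_init__(self) -> None:
        if not 0 < self.input_fraction <= 1:
            raise ValueError("input_fraction must be in (0, 1]")


def delta_cq(target: QpcrMeasurement, housekeeping: QpcrMeasurement) -> float:
    """dCq = mean target Cq - mean housekeeping Cq within one condition."""
    return target.mean_cq - housekeeping.mean_cq


def relative_expression_ddcq(
    target: QpcrMeasurement,
    housekeeping: QpcrMeasurement,
    target_calibrator: QpcrMeasurement,
    housekeeping_calibrator: QpcrMeasurement,
) -> float:
    """2^-ddCq fold change of the sample condition versus the calibrator.

    ddCq = (dCq of the sample) - (dCq of the calibrator). A value of 1
    means no change; 2^-(-3) = 8 means eight-fold up.
    """
    ddcq = delta_cq(target, housekeeping) - delta_cq(
        target_calibrator, housekeeping_calibrator
    )
    return 2.0 ** (-ddcq)


def percent_input(m: ChipMeasurement) -> float:
    """IP recovery as percent of total input chromatin.

    100 x input_fraction x 2^(cq_input - cq_ip): the input Cq is scaled
    up from the measured aliquot to the total, then the Cq difference is
    converted to a quantity ratio assuming perfect doubling.
    """
    return 100.0 * m.input_fraction * 2.0 ** (m.cq_input - m.cq_ip)


def fold_over_reference(percent_target: float, percent_reference: float) -> float:
    """Percent-input ratio over a negative-control locus (set to 1)."""
    if percent_reference <= 0:
        raise ValueError("reference percent input must be positive")
    return percent_target / percent_reference


def t_test_delta_cq(group_a: list[float], group_b: list[float]) -> tuple[float, float]:
    """Unpaired two-tailed Student t-test (pooled variance) on dCq values.

    Returns (t statistic, p-value) with n_a + n_b - 2 degrees of freedom.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >=2 dCq values")
    res = stats.ttest_ind(group_a, group_b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def read_cq_table(path: str | os.PathLike) -> list[QpcrMeasurement]:
    """Read a TSV with columns sample, gene, replicate, cq into grouped
    measurements (replicates collected per sample/gene, input order kept)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "gene", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    out = []
    for (sample, gene), grp in df.groupby(["sample", "gene"], sort=False):
        out.append(QpcrMeasurement(str(sample), str(gene), tuple(float(c) for c in grp["cq"])))
    return out
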