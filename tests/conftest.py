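import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=200)
settings.load_profile("suite")

from g4enrich import GenomeAssembly, GenomicInterval, IntervalSet


@pytest.fixture
def toy_genome():
    """Two small chromosomes; lowercase stretch marks soft-masking."""
    return GenomeAssembly({
        "chr1": "AACGTTGGGTTAGGGTTAGGGTTAGGGACGT",  # telomeric-type G4 at 6..27
        "chr2": "acgtACGTacgtACGTacgtACGT",
    })


@pytest.fixture
def toy_peaks():
    return IntervalSet([
        GenomicInterval("chr1", 0, 31, name="p1"),
        GenomicInterval("chr2", 4, 20, name="p2"),
    ])


@pytest.fixture
def small_sim_config():
    """Scaled-down simulation for fast unit tests (not the default fixture)."""
    from g4enrich import SimulationConfig

    return SimulationConfig(
        n_chroms=2, chrom_length=50_000, n_peaks=40, peak_length=300,
        gc_content=0.35, motif_rate=0.5, g4_rate_peaks=0.5,
        g4_rate_background=0.1, seed=11,
    )
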