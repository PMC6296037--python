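import numpy as np
import pytest

from niptscreen import (
    CHROMOSOMES,
    BinnedSample,
    SimulationParams,
    simulate_control_group,
    simulate_gc_table,
)
from niptscreen.samples import CHROMOSOME_LENGTHS_BP, COMBINED

#: reduced genome for unit tests: one bin per 5 Mb, ~575 autosomal bins
SMALL_BINS = {c: max(4, round(length / 5_000_000))
              for c, length in CHROMOSOME_LENGTHS_BP.items()}


@pytest.fixture(scope="session")
def small_gc_table():
    return simulate_gc_table(SMALL_BINS, seed=11)


@pytest.fixture(scope="session")
def small_params():
    return SimulationParams(n_bins_per_chromosome=dict(SMALL_BINS),
                            total_reads=400_000, seed=17)


@pytest.fixture(scope="session")
def small_group(small_params, small_gc_table):
    return simulate_control_group(12, small_params, small_gc_table)


def build_sample(chrom_counts, sample_id="s", strands=(COMBINED,),
                 bin_size=50_000):
    """One-bin-per-chromosome sample from explicit per-chromosome counts.

    ``chrom_counts`` maps chromosome -> count (split evenly over strands)
    or chromosome -> {strand: count}.  Unlisted chromosomes get 0.
    """
    counts = {}
    for c in CHROMOSOMES:
        spec = chrom_counts.get(c, 0)
        if isinstance(spec, dict):
            counts[c] = {s: np.array([float(spec.get(s, 0))])
                         for s in strands}
        else:
            counts[c] = {s: np.array([float(spec) / len(strands)])
                         for s in strands}
    return BinnedSample(sample_id=sample_id, bin_size=bin_size,
                        counts=counts)


def random_fraction_samples(rng, n, strands=(COMBINED,), scale=100_000):
    """Random one-bin samples with strictly positive counts."""
    samples = []
    for i in range(n):
        chrom_counts = {
            c: {s: float(rng.integers(scale // 2, scale))
                for s in strands}
            for c in CHROMOSOMES
        }
        samples.append(build_sample(chrom_counts, sample_id=f"r{i}",
                                    strands=strands))
    return samples


@pytest.fixture
def sample_factory():
    return build_sample
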