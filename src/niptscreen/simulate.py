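"""Synthetic cfDNA sequencing data with known ground truth.

The generator emulates the count structure of low-coverage whole-genome
cfDNA sequencing as used for prenatal aneuploidy screening:

* a scaled genome whose per-chromosome bin counts are proportional to the
  real chromosome lengths (default: one 50 kb bin per 500 kb of genome,
  about 5 750 autosomal bins) so the full pipeline runs at desk scale
  while preserving the relative chromosome fractions;
* about 10 million reads per sample, multinomially distributed over bins;
* a smooth GC-bias response, count weight proportional to
  ``1 + beta * (gc - 0.5)``;
* bin-level overdispersion via gamma-perturbed bin weights (mean 1,
  relative variance given by the overdispersion parameter), optionally
  inflated further in chosen bins to mimic regions of excess variability;
* a trisomy signal: the affected chromosome's expected weight is scaled by
  ``1 + fetal_fraction/2`` (the placental contribution carries three
  copies instead of two);
* strand-separated counts split binomially 50/50;
* optional chromosome-level count inflation to fabricate low-quality
  outlier samples for quality-control tests.

Every sample carries its exact expected chromosomal fractions in
``sample.truth`` so tests can compare pipeline output against closed-form
ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pysam

from .controlgroup import ControlGroup
from .errors import NiptScreenError
from .samples import (
    AUTOSOMES,
    CHROMOSOMES,
    CHROMOSOME_LENGTHS_BP,
    COMBINED,
    FORWARD,
    REVERSE,
    BinnedSample,
    GCBinTable,
)

#: synthetic genome scale: one 50 kb bin per this many bp of real genome
DEFAULT_SCALE_BP_PER_BIN = 500_000
#: residual Y-chromosome signal (female-fetus pregnancies dominate; only
#: mismapped reads land on Y)
Y_WEIGHT_FACTOR = 0.01


def default_bins_per_chromosome(
        scale_bp_per_bin: int = DEFAULT_SCALE_BP_PER_BIN) -> dict[str, int]:
    return {c: max(1, round(length / scale_bp_per_bin))
            for c, length in CHROMOSOME_LENGTHS_BP.items()}


@dataclass
class SimulationParams:
    """Study conditions for one simulated sample.

    Defaults describe a typical screening run: ~10 M reads, a moderate
    smooth GC bias, and mild bin-level overdispersion on top of the
    multinomial counting noise.
    """

    n_bins_per_chromosome: dict[str, int] = field(
        default_factory=default_bins_per_chromosome)
    total_reads: int = 10_000_000
    gc_bias: float = 0.5
    overdispersion: float = 3e-4
    trisomy: tuple[str, float] | None = None
    outlier_chromosomes: dict[str, float] | None = None
    #: extra per-bin relative weight variance (chromosome -> vector),
    #: added to ``overdispersion``; models regions of excess variability
    bin_variance: dict[str, np.ndarray] | None = None
    separate_strands: bool = True
    bin_size: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise NiptScreenError("total_reads must be positive")
        if self.overdispersion < 0:
            raise NiptScreenError("overdispersion must be >= 0")
        if self.trisomy is not None:
            chrom, ff = self.trisomy
            if not 0 < ff < 1:
                raise NiptScreenError(
                    f"fetal fraction must be in (0, 1), got {ff}")
            self.trisomy = (str(chrom), float(ff))


def simulate_gc_table(
    n_bins_per_chromosome: Mapping[str, int] | None = None,
    bin_size: int = 50_000,
    seed: int = 0,
    gap_fraction: float = 0.02,
) -> GCBinTable:
    """Smooth synthetic per-bin GC content plus a sprinkling of gap bins.

    GC varies slowly along each chromosome (sums of long-period sinusoids
    with random phases, clipped to [0.30, 0.62], around a 0.41 genome-wide
    mean); ``gap_fraction`` of bins are assembly gaps (N fraction 1).
    """
    bins = dict(n_bins_per_chromosome or default_bins_per_chromosome())
    rng = np.random.default_rng(seed)
    gc_fraction, n_fraction = {}, {}
    for chrom in CHROMOSOMES:
        n = bins[chrom]
        i = np.arange(n)
        phases = rng.uniform(0, 2 * np.pi, size=2)
        gc = (0.41
              + 0.07 * np.sin(2 * np.pi * i / 41 + phases[0])
              + 0.04 * np.sin(2 * np.pi * i / 13 + phases[1]))
        gc = np.clip(gc, 0.30, 0.62)
        nf = np.zeros(n)
        n_gaps = int(round(gap_fraction * n))
        if n_gaps:
            gaps = rng.choice(n, size=n_gaps, replace=False)
            nf[gaps] = 1.0
            gc[gaps] = 0.0
        gc_fraction[chrom] = gc
        n_fraction[chrom] = nf
    return GCBinTable(bin_size=bin_size, gc_fraction=gc_fraction,
                      n_fraction=n_fraction)


def _expected_bin_weights(params: SimulationParams,
                          gc_table: GCBinTable) -> dict[str, np.ndarray]:
    """Noise-free expected bin weights (before gamma perturbation)."""
    weights = {}
    for chrom in CHROMOSOMES:
        n = params.n_bins_per_chromosome[chrom]
        gc = gc_table.gc_fraction[chrom][:n]
        nf = gc_table.n_fraction[chrom][:n]
        if len(gc) != n:
            raise NiptScreenError(
                f"GC table has {len(gc)} bins for chromosome {chrom}, "
                f"simulation expects {n}")
        w = 1.0 + params.gc_bias * (gc - 0.5)
        if np.any(w < 0):
            raise NiptScreenError(
                "negative expected bin weights; reduce |gc_bias|")
        w = w.copy()
        w[nf > 0.2] = 0.0
        if chrom == "Y":
            w *= Y_WEIGHT_FACTOR
        if params.trisomy is not None and chrom == params.trisomy[0]:
            w *= 1.0 + params.trisomy[1] / 2.0
        if params.outlier_chromosomes and chrom in params.outlier_chromosomes:
            w *= params.outlier_chromosomes[chrom]
        weights[chrom] = w
    return weights


def expected_fractions(params: SimulationParams,
                       gc_table: GCBinTable) -> dict[str, float]:
    """Closed-form expected autosomal fraction per chromosome."""
    weights = _expected_bin_weights(params, gc_table)
    chrom_w = {c: w.sum() for c, w in weights.items()}
    auto_total = sum(chrom_w[c] for c in AUTOSOMES)
    return {c: chrom_w[c] / auto_total for c in CHROMOSOMES}


def simulate_binned_sample(
    params: SimulationParams,
    gc_table: GCBinTable,
    sample_id: str = "sim",
) -> BinnedSample:
    """Draw one synthetic binned sample under ``params``."""
    rng = np.random.default_rng(params.seed)
    base = _expected_bin_weights(params, gc_table)
    chroms = list(CHROMOSOMES)
    sizes = [len(base[c]) for c in chroms]
    w = np.concatenate([base[c] for c in chroms])

    rel_var = np.zeros_like(w)
    if params.overdispersion > 0:
        rel_var += params.overdispersion
    if params.bin_variance:
        extra = np.concatenate([
            np.asarray(params.bin_variance.get(c, np.zeros(n)))
            for c, n in zip(chroms, sizes)])
        rel_var += extra
    noisy = w.copy()
    perturb = rel_var > 0
    if perturb.any():
        v = rel_var[perturb]
        noisy[perturb] = w[perturb] * rng.gamma(shape=1.0 / v, scale=v)

    counts = rng.multinomial(params.total_reads, noisy / noisy.sum())
    counts = counts.astype(np.float64)

    sample_counts: dict[str, dict[str, np.ndarray]] = {}
    offset = 0
    for chrom, n in zip(chroms, sizes):
        vec = counts[offset:offset + n]
        offset += n
        if params.separate_strands:
            fwd = rng.binomial(vec.astype(np.int64), 0.5).astype(np.float64)
            sample_counts[chrom] = {FORWARD: fwd, REVERSE: vec - fwd}
        else:
            sample_counts[chrom] = {COMBINED: vec}

    return BinnedSample(
        sample_id=sample_id,
        bin_size=params.bin_size,
        counts=sample_counts,
        truth={
            "expected_fractions": expected_fractions(params, gc_table),
            "params": params,
        },
    )


def simulate_control_group(
    n: int,
    params: SimulationParams,
    gc_table: GCBinTable,
    description: str = "simulated control group",
    id_prefix: str = "ctrl",
) -> ControlGroup:
    """Simulate ``n`` euploid-style controls with independent sub-seeds."""
    rng = np.random.default_rng(params.seed)
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    samples = [
        simulate_binned_sample(
            dataclasses.replace(params, seed=int(child_seeds[i])),
            gc_table,
            sample_id=f"{id_prefix}_{i:03d}")
        for i in range(n)
    ]
    return ControlGroup(samples=samples, description=description)


def variance_inflation_map(
    n_bins_per_chromosome: Mapping[str, int],
    fraction_of_bins: float,
    extra_rel_var: float,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Pick a random subset of autosomal bins and give them extra
    relative weight variance (for overdispersed-region scenarios).

    Returns a ``bin_variance`` mapping for :class:`SimulationParams`; the
    same map must be shared by all samples of a group so the excess
    variability is region-specific, not sample-specific.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for chrom in AUTOSOMES:
        n = n_bins_per_chromosome[chrom]
        v = np.zeros(n)
        k = int(round(fraction_of_bins * n))
        if k:
            v[rng.choice(n, size=k, replace=False)] = extra_rel_var
        out[chrom] = v
    return out


# ---------------------------------------------------------------------------
# Toy BAM / FASTA writers
# ---------------------------------------------------------------------------

def write_toy_bam(
    ledger: Mapping[str, Mapping[str, Mapping[int, int]]],
    path: str | Path,
    bin_size: int = 50_000,
    n_bins_per_chromosome: Mapping[str, int] | None = None,
    read_length: int = 36,
) -> Path:
    """Write a coordinate-sorted, indexed BAM realizing an explicit ledger.

    ``ledger`` maps chromosome -> strand ("forward"/"reverse") -> bin index
    -> read count.  Reads are placed at varied offsets within their bin,
    including the first base of the bin, so the half-open bin convention is
    exercised.  The header contains all 24 chromosomes.  Returns the path;
    re-binning the file recovers the ledger exactly.
    """
    path = Path(path)
    bins = dict(n_bins_per_chromosome or default_bins_per_chromosome())
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": f"chr{c}", "LN": bins[c] * bin_size}
               for c in CHROMOSOMES],
    }
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for tid, chrom in enumerate(CHROMOSOMES):
            chrom_len = bins[chrom] * bin_size
            reads: list[tuple[int, bool]] = []
            for strand, per_bin in ledger.get(chrom, {}).items():
                is_reverse = strand == REVERSE
                for bin_idx, count in per_bin.items():
                    if not 0 <= bin_idx < bins[chrom]:
                        raise NiptScreenError(
                            f"ledger bin {bin_idx} outside chromosome "
                            f"{chrom} ({bins[chrom]} bins)")
                    for k in range(count):
                        # deterministic spread over the bin, always keeping
                        # the leftmost base inside the bin
                        offset = (k * 7919 + 11 * bin_idx) % bin_size
                        pos = min(bin_idx * bin_size + offset,
                                  chrom_len - read_length)
                        pos = max(pos, bin_idx * bin_size)
                        reads.append((pos, is_reverse))
            for pos, is_reverse in sorted(reads):
                a = pysam.AlignedSegment()
                a.query_name = f"read_{chrom}_{pos}_{int(is_reverse)}"
                a.query_sequence = "A" * read_length
                a.reference_id = tid
                a.reference_start = pos
                a.mapping_quality = 60
                a.cigartuples = [(0, read_length)]
                a.flag = 16 if is_reverse else 0
                a.query_qualities = pysam.qualitystring_to_array(
                    "I" * read_length)
                bam.write(a)
    pysam.index(str(path))
    return path


def write_synthetic_fasta(
    path: str | Path,
    chrom_lengths: Mapping[str, int],
    seed: int = 0,
    n_run_fraction: float = 0.0,
) -> Path:
    """Random-sequence FASTA over the 24 chromosomes (synthetic reference).

    Bases are i.i.d. A/C/G/T; optionally a leading run of N bases covering
    ``n_run_fraction`` of each chromosome mimics an assembly gap.
    """
    path = Path(path)
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    with open(path, "w") as fh:
        for chrom in CHROMOSOMES:
            length = chrom_lengths[chrom]
            seq = alphabet[rng.integers(0, 4, size=length)]
            n_run = int(round(n_run_fraction * length))
            if n_run:
                seq[:n_run] = ord("N")
            fh.write(f">chr{chrom}\n")
            text = seq.tobytes().decode("ascii")
            for i in range(0, length, 80):
                fh.write(text[i:i + 80] + "\n")
    pysam.faidx(str(path))
    return path
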