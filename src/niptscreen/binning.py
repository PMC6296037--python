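"""BAM binning and reference GC content.

Reads are counted into fixed-width, 0-based half-open bins
``[k*bin_size, (k+1)*bin_size)``; a read belongs to the bin containing its
leftmost aligned base.  Unmapped, secondary and supplementary alignments are
always excluded; duplicate-flagged reads are kept unless requested
otherwise, and no mapping-quality filter is applied by default.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pysam

from .errors import DegenerateInputError, InputError
from .samples import (
    AUTOSOMES,
    CHROMOSOMES,
    COMBINED,
    FORWARD,
    REVERSE,
    BinnedSample,
    GCBinTable,
    normalize_chromosome,
)

logger = logging.getLogger(__name__)


def bin_bam_sample(
    bam_path: str | Path,
    bin_size: int = 50_000,
    separate_strands: bool = False,
    min_mapq: int = 0,
    exclude_duplicates: bool = False,
    sample_id: str | None = None,
) -> BinnedSample:
    """Count aligned reads of a coordinate-sorted, indexed BAM into bins.

    Parameters
    ----------
    bam_path
        Coordinate-sorted BAM with a .bai index whose reference names map
        onto chromosomes 1-22/X/Y ("chr" prefix accepted).
    bin_size
        Bin width in bp (default 50 kb).
    separate_strands
        Count forward- and reverse-strand reads into separate vectors so
        each strand can serve as an independent predictor downstream.
    min_mapq
        Exclude reads below this mapping quality (default 0: no filter).
    exclude_duplicates
        Drop duplicate-flagged reads (kept by default).

    Returns
    -------
    BinnedSample
        Uncorrected sample; unknown contigs are skipped with a logged count.
    """
    bam_path = Path(bam_path)
    if not bam_path.exists():
        raise InputError(f"no such BAM file: {bam_path}")
    try:
        bam = pysam.AlignmentFile(str(bam_path), "rb")
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot open BAM {bam_path}: {exc}") from exc

    strands = (FORWARD, REVERSE) if separate_strands else (COMBINED,)
    counts: dict[str, dict[str, np.ndarray]] = {}
    chrom_to_ref: dict[str, str] = {}
    skipped_contigs = 0
    with bam:
        for ref, length in zip(bam.references, bam.lengths):
            chrom = normalize_chromosome(ref)
            if chrom is None:
                n = bam.count(ref)
                skipped_contigs += n
                continue
            chrom_to_ref[chrom] = ref
            n_bins = math.ceil(length / bin_size)
            counts[chrom] = {s: np.zeros(n_bins) for s in strands}
        missing = [c for c in CHROMOSOMES if c not in counts]
        if missing:
            raise InputError(
                f"BAM {bam_path} lacks chromosomes {missing} in its header")
        if skipped_contigs:
            logger.warning("skipped %d reads on unrecognized contigs in %s",
                           skipped_contigs, bam_path)

        for chrom in CHROMOSOMES:
            vecs = counts[chrom]
            for read in bam.fetch(chrom_to_ref[chrom]):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if read.mapping_quality < min_mapq:
                    continue
                if exclude_duplicates and read.is_duplicate:
                    continue
                bin_idx = read.reference_start // bin_size
                if separate_strands:
                    strand = REVERSE if read.is_reverse else FORWARD
                else:
                    strand = COMBINED
                vecs[strand][bin_idx] += 1

    sample = BinnedSample(
        sample_id=sample_id or bam_path.stem,
        bin_size=bin_size,
        counts=counts,
    )
    if sample.total_autosomal_reads() == 0:
        raise DegenerateInputError(
            f"BAM {bam_path} has no usable reads on any autosome")
    return sample


def compute_gc_table(fasta_path: str | Path, bin_size: int = 50_000) -> GCBinTable:
    """Per-bin GC fraction (over non-N bases) and N fraction from a FASTA.

    The last, possibly partial bin of each chromosome uses its actual
    length.  A bin with no unambiguous base reports GC fraction 0.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise InputError(f"no such FASTA file: {fasta_path}")
    fasta = pysam.FastaFile(str(fasta_path))
    ref_for = {}
    for ref in fasta.references:
        chrom = normalize_chromosome(ref)
        if chrom is not None:
            ref_for[chrom] = ref

    gc_fraction: dict[str, np.ndarray] = {}
    n_fraction: dict[str, np.ndarray] = {}
    with fasta:
        for chrom in CHROMOSOMES:
            if chrom not in ref_for:
                raise InputError(
                    f"chromosome {chrom} missing from FASTA {fasta_path}")
            seq = fasta.fetch(ref_for[chrom]).upper().encode("ascii")
            arr = np.frombuffer(seq, dtype=np.uint8)
            n_bins = math.ceil(len(arr) / bin_size)
            starts = np.arange(n_bins) * bin_size
            ends = np.minimum(starts + bin_size, len(arr))
            lengths = (ends - starts).astype(np.float64)

            def per_bin(base: bytes) -> np.ndarray:
                hits = (arr == base[0]).astype(np.int64)
                csum = np.concatenate(([0], np.cumsum(hits)))
                return (csum[ends] - csum[starts]).astype(np.float64)

            g, c = per_bin(b"G"), per_bin(b"C")
            a, t = per_bin(b"A"), per_bin(b"T")
            acgt = a + c + g + t
            with np.errstate(invalid="ignore", divide="ignore"):
                gc = np.where(acgt > 0, (g + c) / np.maximum(acgt, 1), 0.0)
            gc_fraction[chrom] = gc
            n_fraction[chrom] = (lengths - acgt) / lengths
    return GCBinTable(bin_size=bin_size, gc_fraction=gc_fraction,
                      n_fraction=n_fraction)
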