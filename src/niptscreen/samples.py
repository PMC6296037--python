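"""Core containers: binned samples, per-bin GC tables, chromosomal fractions.

A *binned sample* is one sequenced cfDNA sample reduced to read counts in
fixed-width genomic bins (default 50 kb), kept per chromosome and optionally
per strand.  All downstream statistics (Z-score, NCV, regression-based
Z-score, Match QC) operate on the *chromosomal fractions* derived from these
counts: reads on a chromosome divided by the total autosomal read count.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputError

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
SEX_CHROMOSOMES: tuple[str, ...] = ("X", "Y")
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + SEX_CHROMOSOMES

FORWARD = "forward"
REVERSE = "reverse"
COMBINED = "combined"

UNCORRECTED = "Uncorrected"
GC_CORRECTED = "GC Corrected"
LOESS_GC_CORRECTED = "LOESS GC Corrected"
CHI_CORRECTED = "Chi Corrected"

#: GRCh37 chromosome lengths in bp; used for default bin geometry and for
#: scaled synthetic genomes that preserve relative chromosome sizes.
CHROMOSOME_LENGTHS_BP: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560, "Y": 59_373_566,
}


def normalize_chromosome(name: str) -> str | None:
    """Map a reference name onto the canonical 1-22/X/Y labels.

    Accepts "chr"-prefixed and bare names; returns ``None`` for contigs that
    are not one of the 24 nuclear chromosomes (chrM, scaffolds, ...).
    """
    base = name[3:] if name.lower().startswith("chr") else name
    base = base.upper() if base.upper() in SEX_CHROMOSOMES else base
    return base if base in CHROMOSOMES else None


def chromosome_sort_key(chrom: str) -> tuple[int, str]:
    return (int(chrom), "") if chrom in AUTOSOMES else (100, chrom)


@dataclass
class BinnedSample:
    """Per-bin read counts for one sample, with correction bookkeeping.

    ``counts`` maps chromosome -> strand -> float vector of per-bin counts.
    Strand keys are ``forward``/``reverse`` when strand-separated, else the
    single key ``combined``.  Raw counts are integral; corrected counts may
    not be.  The correction-status lists record, in order, which variation
    reduction steps have been applied to the autosomes and to the sex
    chromosomes.
    """

    sample_id: str
    bin_size: int
    counts: dict[str, dict[str, np.ndarray]]
    autosomal_correction_status: list[str] = field(
        default_factory=lambda: [UNCORRECTED])
    sex_correction_status: list[str] = field(
        default_factory=lambda: [UNCORRECTED])
    #: simulation ground truth (expected fractions etc.); never serialized
    truth: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for chrom, strands in self.counts.items():
            for strand, vec in strands.items():
                strands[strand] = np.asarray(vec, dtype=np.float64)

    # -- geometry ---------------------------------------------------------

    @property
    def strands(self) -> tuple[str, ...]:
        first = self.counts[AUTOSOMES[0]]
        return tuple(sorted(first.keys()))

    @property
    def strand_separated(self) -> bool:
        return COMBINED not in self.strands

    def n_bins(self, chrom: str) -> int:
        return len(next(iter(self.counts[chrom].values())))

    def validate(self) -> None:
        missing = [c for c in CHROMOSOMES if c not in self.counts]
        if missing:
            raise InputError(f"sample {self.sample_id!r} lacks chromosomes "
                             f"{missing}")
        for chrom in CHROMOSOMES:
            lengths = {len(v) for v in self.counts[chrom].values()}
            if len(lengths) != 1:
                raise InputError(
                    f"strand vectors of chromosome {chrom} differ in length")
            for vec in self.counts[chrom].values():
                if np.any(vec < 0):
                    raise InputError(
                        f"negative counts on chromosome {chrom}")

    # -- aggregation ------------------------------------------------------

    def chromosome_reads(self, chrom: str, strand: str | None = None) -> float:
        if strand is not None:
            return float(self.counts[chrom][strand].sum())
        return float(sum(v.sum() for v in self.counts[chrom].values()))

    def total_autosomal_reads(self) -> float:
        return float(sum(self.chromosome_reads(c) for c in AUTOSOMES))

    def copy(self, sample_id: str | None = None) -> "BinnedSample":
        return BinnedSample(
            sample_id=sample_id or self.sample_id,
            bin_size=self.bin_size,
            counts={c: {s: v.copy() for s, v in strands.items()}
                    for c, strands in self.counts.items()},
            autosomal_correction_status=list(self.autosomal_correction_status),
            sex_correction_status=list(self.sex_correction_status),
            truth=self.truth,
        )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "bin_size": self.bin_size,
            "autosomal_correction_status": self.autosomal_correction_status,
            "sex_correction_status": self.sex_correction_status,
            "counts": {c: {s: v.tolist() for s, v in strands.items()}
                       for c, strands in self.counts.items()},
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "BinnedSample":
        return cls(
            sample_id=data["sample_id"],
            bin_size=int(data["bin_size"]),
            counts={c: {s: np.asarray(v, dtype=np.float64)
                        for s, v in strands.items()}
                    for c, strands in data["counts"].items()},
            autosomal_correction_status=list(
                data["autosomal_correction_status"]),
            sex_correction_status=list(data["sex_correction_status"]),
        )

    def save(self, path: str | Path) -> None:
        _write_json(self.to_dict(), path)

    @classmethod
    def load(cls, path: str | Path) -> "BinnedSample":
        return cls.from_dict(_read_json(path))


@dataclass
class GCBinTable:
    """Per-bin GC fraction and N fraction computed from a reference FASTA.

    ``gc_fraction`` is (G+C)/(A+C+G+T) over the bin's non-N bases;
    ``n_fraction`` is the share of N (ambiguous/gap) bases.  Bins dominated
    by assembly gaps are excluded from GC-correction fits downstream.
    """

    bin_size: int
    gc_fraction: dict[str, np.ndarray]
    n_fraction: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.gc_fraction = {c: np.asarray(v, dtype=np.float64)
                            for c, v in self.gc_fraction.items()}
        self.n_fraction = {c: np.asarray(v, dtype=np.float64)
                           for c, v in self.n_fraction.items()}

    def n_bins(self, chrom: str) -> int:
        return len(self.gc_fraction[chrom])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.gc_fraction, key=chromosome_sort_key):
            gc, nf = self.gc_fraction[chrom], self.n_fraction[chrom]
            rows.append(pd.DataFrame({
                "chromosome": chrom,
                "bin_index": np.arange(len(gc)),
                "gc_fraction": gc,
                "n_fraction": nf,
            }))
        return pd.concat(rows, ignore_index=True)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "GCBinTable":
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
        gc, nf = {}, {}
        for chrom, sub in df.groupby("chromosome", sort=False):
            sub = sub.sort_values("bin_index")
            gc[chrom] = sub["gc_fraction"].to_numpy()
            nf[chrom] = sub["n_fraction"].to_numpy()
        # bin size is not recoverable from the TSV; callers that need it
        # should keep the table object.  Stored as 0 on reload.
        return cls(bin_size=0, gc_fraction=gc, n_fraction=nf)


@dataclass
class FractionVector:
    """Chromosomal fractions of one sample.

    Every fraction, including those of X and Y, uses the same denominator:
    the total read count over all autosomes and strands.  Autosomal
    fractions therefore sum to one.
    """

    fractions: dict[tuple[str, str], float]
    denominator_reads: float

    def chromosome(self, chrom: str) -> float:
        """Strand-summed fraction of one chromosome."""
        return sum(v for (c, _s), v in self.fractions.items() if c == chrom)


def chromosomal_fractions(sample: BinnedSample) -> FractionVector:
    """Per-(chromosome, strand) read fractions with autosomal denominator."""
    total = sample.total_autosomal_reads()
    if total <= 0:
        raise DegenerateInputError(
            f"sample {sample.sample_id!r} has no autosomal reads")
    fractions = {
        (chrom, strand): float(vec.sum()) / total
        for chrom in CHROMOSOMES
        for strand, vec in sample.counts[chrom].items()
    }
    return FractionVector(fractions=fractions, denominator_reads=total)


def bins_for_length(length_bp: int, bin_size: int) -> int:
    return math.ceil(length_bp / bin_size)


def _write_json(obj: dict, path: str | Path) -> None:
    path = Path(path)
    text = json.dumps(obj, sort_keys=True)
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        path.write_text(text)


def _read_json(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            return json.load(fh)
    return json.loads(path.read_text())
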