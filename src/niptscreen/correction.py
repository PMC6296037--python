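"""Variation reduction: GC-bias correction and chi-squared bin reduction.

Two sources of unwanted variability are handled before prediction:

* **GC bias** — amplification/sequencing efficiency depends smoothly on a
  bin's GC content.  Two corrections are offered: *weighted-bin* (bins are
  grouped by rounded GC fraction and each group's counts rescaled so that
  its mean equals the global mean of usable bins) and *LOESS* (a locally
  weighted regression of count on GC fraction supplies the per-bin scaling).

* **Chi-squared variation reduction** — some genomic regions vary between
  samples far more than counting statistics allow.  After putting all
  control samples on a common depth, a per-bin chi-squared statistic over
  the controls measures excess variability; bins whose normal-approximation
  score exceeds a cutoff are down-weighted by their variance-inflation
  factor chi2/df in both the test sample and every control.

Both corrections operate per strand when counts are strand-separated, and
build their weights from autosomal bins only; X/Y receive the
autosome-derived correction only when explicitly requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .controlgroup import ControlGroup
from .errors import (
    DegenerateInputError,
    DegenerateStatisticsError,
    StatusMismatchError,
)
from .samples import (
    AUTOSOMES,
    CHI_CORRECTED,
    GC_CORRECTED,
    LOESS_GC_CORRECTED,
    SEX_CHROMOSOMES,
    UNCORRECTED,
    BinnedSample,
    GCBinTable,
)

#: bins with a larger share of ambiguous (N) reference bases are assembly
#: gaps (centromeres/telomeres) and carry no usable signal
MAX_N_FRACTION = 0.2
#: GC grouping width for the weighted-bin method (one percentage point)
GC_GROUP_WIDTH = 0.01
#: GC groups with fewer usable bins than this are zeroed rather than scaled
MIN_BINS_PER_GROUP = 10


# ---------------------------------------------------------------------------
# GC correction
# ---------------------------------------------------------------------------

def gc_correct(
    target: BinnedSample | ControlGroup,
    gc_table: GCBinTable,
    method: str = "bin",
    include_XY: bool = False,
    span: float = 0.75,
    group_width: float = GC_GROUP_WIDTH,
    min_bins_per_group: int = MIN_BINS_PER_GROUP,
):
    """GC-correct a sample or every member of a control group.

    ``method`` is ``"bin"`` (weighted-bin) or ``"loess"``.  The target must
    be uncorrected; the appropriate label is appended to the autosomal
    correction status (and to the sex status when ``include_XY``).
    """
    if method not in ("bin", "loess", "LOESS"):
        raise ValueError(f"unknown GC-correction method {method!r}")
    if isinstance(target, ControlGroup):
        corrected = [
            gc_correct(s, gc_table, method=method, include_XY=include_XY,
                       span=span, group_width=group_width,
                       min_bins_per_group=min_bins_per_group)
            for s in target.samples
        ]
        return ControlGroup(samples=corrected, description=target.description)

    sample = target
    if sample.autosomal_correction_status != [UNCORRECTED]:
        raise StatusMismatchError(
            f"sample {sample.sample_id!r} is already corrected "
            f"({sample.autosomal_correction_status}); GC correction applies "
            "to uncorrected samples only")
    for chrom in sample.counts:
        if sample.n_bins(chrom) != gc_table.n_bins(chrom):
            raise StatusMismatchError(
                f"GC table geometry does not match sample bins on "
                f"chromosome {chrom}")

    out = sample.copy()
    label = GC_CORRECTED if method == "bin" else LOESS_GC_CORRECTED
    for strand in sample.strands:
        auto_counts = np.concatenate(
            [sample.counts[c][strand] for c in AUTOSOMES])
        auto_gc = np.concatenate([gc_table.gc_fraction[c] for c in AUTOSOMES])
        auto_nf = np.concatenate([gc_table.n_fraction[c] for c in AUTOSOMES])
        usable = auto_nf <= MAX_N_FRACTION
        if not usable.any():
            raise DegenerateInputError("no usable autosomal bins (all gaps)")
        if method == "bin":
            weight_of = _bin_weight_function(
                auto_counts[usable], auto_gc[usable],
                group_width, min_bins_per_group)
        else:
            weight_of = _loess_weight_function(
                auto_counts[usable], auto_gc[usable], span)
        chroms = AUTOSOMES + (SEX_CHROMOSOMES if include_XY else ())
        for chrom in chroms:
            gc = gc_table.gc_fraction[chrom]
            nf = gc_table.n_fraction[chrom]
            w = weight_of(gc)
            w[nf > MAX_N_FRACTION] = 0.0
            out.counts[chrom][strand] = sample.counts[chrom][strand] * w
    out.autosomal_correction_status.append(label)
    if include_XY:
        out.sex_correction_status.append(label)
    return out


def _bin_weight_function(counts, gc, group_width, min_bins_per_group):
    """Weighted-bin method: w_g = global mean / group-g mean.

    Groups below the size floor or with zero mean get weight 0, excluding
    those bins from all downstream statistics while keeping the vector
    geometry intact.
    """
    groups = np.round(gc / group_width).astype(np.int64)
    global_mean = counts.mean()
    sums: dict[int, float] = {}
    sizes: dict[int, int] = {}
    for g, c in zip(groups, counts):
        sums[g] = sums.get(g, 0.0) + c
        sizes[g] = sizes.get(g, 0) + 1
    weights = {
        g: (global_mean * sizes[g] / sums[g]
            if sizes[g] >= min_bins_per_group and sums[g] > 0 else 0.0)
        for g in sums
    }

    def weight_of(gc_values: np.ndarray) -> np.ndarray:
        keys = np.round(gc_values / group_width).astype(np.int64)
        return np.array([weights.get(k, 0.0) for k in keys])

    return weight_of


def _loess_weight_function(counts, gc, span):
    """LOESS method: w(gc) = global mean / fitted(gc), fitted floored."""
    global_mean = counts.mean()
    fitted = lowess(counts, gc, frac=span, return_sorted=True)
    xs, idx = np.unique(fitted[:, 0], return_index=True)
    ys = fitted[:, 1][idx]
    eps = max(global_mean * 1e-6, 1e-12)

    def weight_of(gc_values: np.ndarray) -> np.ndarray:
        f = np.interp(gc_values, xs, ys)
        return global_mean / np.maximum(f, eps)

    return weight_of


# ---------------------------------------------------------------------------
# Chi-squared variation reduction
# ---------------------------------------------------------------------------

@dataclass
class ChiSquareBinReport:
    """Per-bin chi-squared statistics over the (depth-scaled) controls.

    ``normalized_score`` is the normal approximation (chi2 - df)/sqrt(2 df);
    bins exceeding ``cutoff`` are flagged and divided by ``chi2/df``.  Bins
    whose expected count is zero are skipped (NaN score, never flagged).
    """

    chi_statistic: dict[tuple[str, str], np.ndarray]
    degrees_of_freedom: int
    normalized_score: dict[tuple[str, str], np.ndarray]
    flagged: set[tuple[str, str, int]]
    cutoff: float

    def divisors(self, chrom: str, strand: str) -> np.ndarray:
        chi = self.chi_statistic[(chrom, strand)]
        div = np.ones_like(chi)
        for (c, s, b) in self.flagged:
            if c == chrom and s == strand:
                div[b] = chi[b] / self.degrees_of_freedom
        return div

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (chrom, strand), chi in sorted(self.chi_statistic.items()):
            score = self.normalized_score[(chrom, strand)]
            div = self.divisors(chrom, strand)
            flag = np.array([(chrom, strand, b) in self.flagged
                             for b in range(len(chi))])
            rows.append(pd.DataFrame({
                "chromosome": chrom, "bin": np.arange(len(chi)),
                "strand": strand, "chi2": chi, "normalized_score": score,
                "flagged": flag, "divisor": div,
            }))
        return pd.concat(rows, ignore_index=True)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def chi_square_bin_statistics(matrix: np.ndarray) -> tuple[np.ndarray, int]:
    """Chi-squared statistic per bin (column) across samples (rows).

    chi2_b = sum_s (x_sb - E_b)^2 / E_b with E_b the column mean; columns
    with E_b = 0 yield NaN.  df = n_samples - 1.
    """
    n = matrix.shape[0]
    expected = matrix.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi = ((matrix - expected) ** 2 / expected).sum(axis=0)
    chi[expected == 0] = np.nan
    return chi, n - 1


def chi_correct(
    sample: BinnedSample,
    group: ControlGroup,
    cutoff_sd: float = 3.5,
    include_XY: bool = False,
) -> tuple[BinnedSample, ControlGroup, ChiSquareBinReport]:
    """Chi-squared variation reduction of a sample against its controls.

    The control samples are first scaled to the group's mean total
    autosomal depth; the per-bin chi-squared statistic is then computed
    over the controls only (the test sample never contributes to the
    expectation, so a trisomy cannot dilute its own evidence).  Flagged
    bins are divided by chi2/df in the test sample and in every scaled
    control.
    """
    if sample.autosomal_correction_status != group.autosomal_correction_status:
        raise StatusMismatchError(
            "sample and control group must share an identical correction "
            f"status (sample: {sample.autosomal_correction_status}, group: "
            f"{group.autosomal_correction_status})")
    if CHI_CORRECTED in sample.autosomal_correction_status:
        raise StatusMismatchError(
            "chi-squared variation reduction already applied")
    if sample.bin_size != group.bin_size or sample.strands != group.strands:
        raise StatusMismatchError(
            "sample and control group differ in bin size or strand mode")
    if len(group) < 3:
        raise DegenerateStatisticsError(
            f"chi-squared variation reduction needs >= 3 controls, got "
            f"{len(group)}")

    scaled_group = scale_group_to_mean_depth(group)
    chroms = AUTOSOMES + (SEX_CHROMOSOMES if include_XY else ())

    chi_map: dict[tuple[str, str], np.ndarray] = {}
    score_map: dict[tuple[str, str], np.ndarray] = {}
    flagged: set[tuple[str, str, int]] = set()
    df = len(group) - 1
    norm = math.sqrt(2 * df)
    for chrom in chroms:
        for strand in group.strands:
            matrix = np.vstack(
                [s.counts[chrom][strand] for s in scaled_group.samples])
            chi, _ = chi_square_bin_statistics(matrix)
            score = (chi - df) / norm
            chi_map[(chrom, strand)] = chi
            score_map[(chrom, strand)] = score
            for b in np.flatnonzero(score > cutoff_sd):
                flagged.add((chrom, strand, int(b)))

    report = ChiSquareBinReport(
        chi_statistic=chi_map, degrees_of_freedom=df,
        normalized_score=score_map, flagged=flagged, cutoff=cutoff_sd)

    corrected_sample = apply_chi_correction(sample, report,
                                            include_XY=include_XY)
    corrected_members = [
        apply_chi_correction(s, report, include_XY=include_XY)
        for s in scaled_group.samples
    ]
    corrected_group = ControlGroup(samples=corrected_members,
                                   description=group.description)
    return corrected_sample, corrected_group, report


def scale_group_to_mean_depth(group: ControlGroup) -> ControlGroup:
    """Scale every member so its total autosomal count equals the group mean."""
    totals = np.array([s.total_autosomal_reads() for s in group.samples])
    target = totals.mean()
    scaled = []
    for s, tot in zip(group.samples, totals):
        factor = target / tot
        c = s.copy()
        for chrom in c.counts:
            for strand in c.counts[chrom]:
                c.counts[chrom][strand] = c.counts[chrom][strand] * factor
        scaled.append(c)
    return ControlGroup(samples=scaled, description=group.description)


def apply_chi_correction(sample: BinnedSample, report: ChiSquareBinReport,
                         include_XY: bool = False) -> BinnedSample:
    """Divide flagged bins by chi2/df; unflagged bins are untouched."""
    out = sample.copy()
    for (chrom, strand, b) in report.flagged:
        chi = report.chi_statistic[(chrom, strand)][b]
        out.counts[chrom][strand][b] /= chi / report.degrees_of_freedom
    out.autosomal_correction_status.append(CHI_CORRECTED)
    if include_XY:
        out.sex_correction_status.append(CHI_CORRECTED)
    return out
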