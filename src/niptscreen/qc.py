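"""Quality control: control-group representativeness and internal health.

* **Match QC** — for a test sample, the sum of squared differences in
  autosomal chromosomal fractions against each control; the mean of these
  sums is the sample's match score.  A score more than 3 SD from the
  controls' own (leave-one-out) match scores indicates the group is not
  representative for the sample.
* **Diagnostics** — every control is scored against the remaining controls
  with the standard Z-score, per chromosome and strand.  Samples with more
  than one aberrant entry (|Z| > 3) are flagged as removal candidates; the
  per-chromosome Z columns are summarized by mean, SD and Shapiro-Wilk P.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .controlgroup import ControlGroup
from .errors import DegenerateStatisticsError, NiptScreenError
from .prediction import _check_statuses, _shapiro_p, control_fraction_matrix
from .samples import AUTOSOMES, BinnedSample, chromosomal_fractions

Z_BOUND = 3.0


@dataclass
class MatchQCResult:
    per_control_ss: dict[str, float]
    match_score: float
    group_match_mean: float
    group_match_sd: float
    flagged: bool

    def to_dict(self) -> dict:
        return {
            "per_control_ss": self.per_control_ss,
            "match_score": self.match_score,
            "group_match_mean": self.group_match_mean,
            "group_match_sd": self.group_match_sd,
            "flagged": self.flagged,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": list(self.per_control_ss),
            "sum_of_squares": list(self.per_control_ss.values()),
        })


def _fraction_rows(group: ControlGroup) -> np.ndarray:
    matrix, _ = control_fraction_matrix(
        group, strand_summed=not group.samples[0].strand_separated)
    return matrix


def _sample_fraction_row(sample: BinnedSample) -> np.ndarray:
    fv = chromosomal_fractions(sample)
    if sample.strand_separated:
        return np.array([fv.fractions[(c, s)]
                         for c in AUTOSOMES for s in sample.strands])
    return np.array([fv.chromosome(c) for c in AUTOSOMES])


def match_control_group(
    sample: BinnedSample,
    group: ControlGroup,
    mode: str = "report",
    n_of_samples: int | None = None,
):
    """Match QC report or best-matching subset selection.

    ``mode="report"`` returns a :class:`MatchQCResult`; ``mode="subset"``
    returns a new control group of the ``n_of_samples`` controls with the
    smallest sum of squared fraction differences to the sample.
    """
    _check_statuses(sample, group)
    sample_row = _sample_fraction_row(sample)
    control_rows = _fraction_rows(group)
    ss = ((control_rows - sample_row) ** 2).sum(axis=1)

    if mode == "subset":
        if n_of_samples is None or not 2 <= n_of_samples <= len(group):
            raise NiptScreenError(
                f"n_of_samples must be in [2, {len(group)}], got "
                f"{n_of_samples}")
        order = np.argsort(ss, kind="stable")[:n_of_samples]
        return ControlGroup(
            samples=[group.samples[i] for i in sorted(order)],
            description=group.description)
    if mode != "report":
        raise NiptScreenError(f"unknown Match QC mode {mode!r}")

    # reference distribution: each control's own match score against the
    # remaining controls
    pair_ss = ((control_rows[:, None, :] - control_rows[None, :, :]) ** 2
               ).sum(axis=2)
    n = len(group)
    control_scores = (pair_ss.sum(axis=1)) / (n - 1)  # diagonal is zero
    match_score = float(ss.mean())
    group_mean = float(control_scores.mean())
    group_sd = float(control_scores.std(ddof=1))
    return MatchQCResult(
        per_control_ss={sid: float(v)
                        for sid, v in zip(group.sample_ids, ss)},
        match_score=match_score,
        group_match_mean=group_mean,
        group_match_sd=group_sd,
        flagged=bool(abs(match_score - group_mean) > 3 * group_sd),
    )


@dataclass
class DiagnosticsReport:
    """Leave-one-out Z-scores of every control, per chromosome and strand."""

    z_matrix: dict[tuple[str, str, str], float]  # (sample_id, chrom, strand)
    abnormal: list[tuple[str, str, str, float]]
    column_statistics: dict[tuple[str, str], dict[str, float]]
    removal_candidates: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sample_id": sid, "chromosome": c, "strand": s, "z": z}
                for (sid, c, s), z in self.z_matrix.items()]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "abnormal": [list(entry) for entry in self.abnormal],
            "removal_candidates": self.removal_candidates,
            "column_statistics": {
                f"{c}:{s}": stats
                for (c, s), stats in self.column_statistics.items()
            },
        }


def diagnose_control_group(group: ControlGroup) -> DiagnosticsReport:
    """Score every control against the others and flag outlier samples.

    Uses the same standardization as the Z-score statistic: each held-out
    sample's (chromosome, strand) fraction against the mean and (n-1) SD
    of the remaining controls.  A sample with more than one aberrant entry
    (|Z| > 3) is a removal candidate.
    """
    if len(group) < 4:
        raise DegenerateStatisticsError(
            f"diagnostics need >= 4 controls, got {len(group)}")
    strands = group.strands
    matrix, entities = control_fraction_matrix(group, strand_summed=False)
    n = len(group)

    z_matrix: dict[tuple[str, str, str], float] = {}
    abnormal: list[tuple[str, str, str, float]] = []
    column_stats: dict[tuple[str, str], dict[str, float]] = {}
    counts_abnormal: dict[str, int] = {sid: 0 for sid in group.sample_ids}

    for j, (chrom, strand) in enumerate(entities):
        col = matrix[:, j]
        zs = np.empty(n)
        for i in range(n):
            rest = np.delete(col, i)
            sd = rest.std(ddof=1)
            if sd == 0:
                raise DegenerateStatisticsError(
                    f"zero leave-one-out SD on chromosome {chrom} "
                    f"({strand} strand)")
            zs[i] = (col[i] - rest.mean()) / sd
        for sid, z in zip(group.sample_ids, zs):
            z_matrix[(sid, chrom, strand)] = float(z)
            if abs(z) > Z_BOUND:
                abnormal.append((sid, chrom, strand, float(z)))
                counts_abnormal[sid] += 1
        column_stats[(chrom, strand)] = {
            "mean": float(zs.mean()),
            "sd": float(zs.std(ddof=1)),
            "shapiro_p": _shapiro_p(zs),
        }

    removal = [sid for sid in group.sample_ids if counts_abnormal[sid] > 1]
    return DiagnosticsReport(
        z_matrix=z_matrix,
        abnormal=abnormal,
        column_statistics=column_stats,
        removal_candidates=removal,
    )
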