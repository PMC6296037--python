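"""Trisomy prediction statistics: Z-score, NCV and regression-based Z.

All three compare the observed read fraction of a chromosome of interest in
a test sample with the fraction expected from a control group of euploid
samples; a score outside the -3..3 range is the conventional trisomy call.

* **Z-score** — the chromosomal fraction itself, standardized by the
  control group's mean and (n-1) SD.
* **NCV** (normalized chromosome value) — the ratio of the chromosome of
  interest to a denominator set of reference chromosomes, with the
  denominator set chosen once per control group to minimize the ratio's
  coefficient of variation.  The expensive denominator search lives in
  ``prepare_ncv``; scoring a sample against the stored template is cheap.
* **RBZ** (regression-based Z) — the chromosome's fraction is predicted
  from other chromosomes' fractions (forward and reverse strands as
  separate predictors) by forward-stepwise linear regression fitted on a
  train split of the controls; the score standardizes the observed/predicted
  ratio using the test split's coefficient of variation.

Chromosomes 13, 18 and 21 are the common trisomy candidates and are
excluded as predictors/denominators by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .controlgroup import ControlGroup
from .errors import (
    DegenerateStatisticsError,
    NiptScreenError,
    StatusMismatchError,
)
from .samples import AUTOSOMES, BinnedSample, chromosomal_fractions

DEFAULT_TRISOMY_CANDIDATES = frozenset({"13", "18", "21"})
PRACTICAL_CV = "Practical CV"
THEORETICAL_CV = "Theoretical CV"


def _shapiro_p(values: np.ndarray) -> float:
    if len(values) < 3 or np.ptp(values) == 0:
        return float("nan")
    return float(stats.shapiro(values).pvalue)


def _check_statuses(sample: BinnedSample, group: ControlGroup) -> None:
    if (sample.autosomal_correction_status != group.autosomal_correction_status
            or sample.bin_size != group.bin_size
            or sample.strands != group.strands):
        raise StatusMismatchError(
            "sample and control group must share bin size, strand mode and "
            f"correction status (sample: "
            f"{sample.autosomal_correction_status}/{sample.strands}, group: "
            f"{group.autosomal_correction_status}/{group.strands})")


# ---------------------------------------------------------------------------
# Standard Z-score
# ---------------------------------------------------------------------------

@dataclass
class ZScoreResult:
    chromosome: str
    z_score: float
    sample_fraction: float
    control_mean: float
    control_sd: float
    shapiro_p: float
    n_controls: int

    def summary(self) -> str:
        return (
            f"Z-score chromosome {self.chromosome}: {self.z_score:.4f}\n"
            f"control_group_statistics: mean {self.control_mean:.6e}  "
            f"SD {self.control_sd:.6e}  Shapiro_P_value {self.shapiro_p:.4f}"
            f"  (n = {self.n_controls})"
        )

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "z_score": self.z_score,
            "sample_fraction": self.sample_fraction,
            "control_group_statistics": {
                "mean": self.control_mean,
                "SD": self.control_sd,
                "Shapiro_P_value": self.shapiro_p,
            },
            "n_controls": self.n_controls,
        }


def control_fraction_matrix(group: ControlGroup,
                            strand_summed: bool = True) -> tuple[np.ndarray, list]:
    """Autosomal fraction matrix (controls x entities) and the entity list.

    Entities are chromosomes when ``strand_summed`` else (chromosome,
    strand) pairs; the denominator of every fraction is the sample's total
    autosomal count over all strands.
    """
    entities: list = (
        list(AUTOSOMES) if strand_summed
        else [(c, s) for c in AUTOSOMES for s in group.strands]
    )
    rows = []
    for s in group.samples:
        fv = chromosomal_fractions(s)
        if strand_summed:
            rows.append([fv.chromosome(c) for c in entities])
        else:
            rows.append([fv.fractions[e] for e in entities])
    return np.asarray(rows), entities


def calculate_z_score(sample: BinnedSample, group: ControlGroup,
                      chromosome: str) -> ZScoreResult:
    """Standard Z-score of a chromosome's autosomal read fraction."""
    chromosome = str(chromosome)
    _check_statuses(sample, group)
    if len(group) < 3:
        raise DegenerateStatisticsError(
            f"Z-score needs >= 3 controls, got {len(group)}")
    control_fracs = np.array(
        [chromosomal_fractions(s).chromosome(chromosome)
         for s in group.samples])
    sample_frac = chromosomal_fractions(sample).chromosome(chromosome)
    mean = float(control_fracs.mean())
    sd = float(control_fracs.std(ddof=1))
    if sd == 0:
        raise DegenerateStatisticsError(
            f"control fractions of chromosome {chromosome} have zero SD")
    return ZScoreResult(
        chromosome=chromosome,
        z_score=(sample_frac - mean) / sd,
        sample_fraction=sample_frac,
        control_mean=mean,
        control_sd=sd,
        shapiro_p=_shapiro_p(control_fracs),
        n_controls=len(group),
    )


# ---------------------------------------------------------------------------
# Normalized chromosome value
# ---------------------------------------------------------------------------

@dataclass
class NCVTemplate:
    """A chromosome of interest with its CV-minimizing denominator set."""

    chromosome: str
    denominators: tuple[str, ...]
    control_ratios: np.ndarray
    cv: float
    control_mean: float
    control_sd: float
    shapiro_p: float
    max_denominators: int
    train_test_used: bool
    correction_status: list[str] = field(default_factory=list)
    degenerate: bool = False

    def sample_ratio(self, sample: BinnedSample) -> float:
        num = sample.chromosome_reads(self.chromosome)
        den = sum(sample.chromosome_reads(d) for d in self.denominators)
        if den == 0:
            raise DegenerateStatisticsError(
                f"sample has no reads on denominator chromosomes "
                f"{self.denominators}")
        return num / den


@dataclass
class NCVResult:
    chromosome: str
    ncv_score: float
    sample_ratio: float
    control_mean: float
    control_sd: float
    shapiro_p: float
    n_controls: int
    denominators: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "ncv_score": self.ncv_score,
            "sample_ratio": self.sample_ratio,
            "denominators": list(self.denominators),
            "control_group_statistics": {
                "mean": self.control_mean,
                "SD": self.control_sd,
                "Shapiro_P_value": self.shapiro_p,
            },
            "n_controls": self.n_controls,
        }


def _subset_sort_key(subset: Iterable[str]) -> tuple:
    return tuple(sorted(int(c) for c in subset))


def prepare_ncv(
    group: ControlGroup,
    chromosome: str,
    max_denominators: int = 9,
    exclude: Iterable[str] = DEFAULT_TRISOMY_CANDIDATES,
    use_test_train_set: bool = False,
    train_fraction: float = 0.6,
    seed: int | None = None,
    max_subsets: int = 10 ** 6,
) -> NCVTemplate:
    """Search all denominator subsets for the CV-minimizing NCV template.

    Over every non-empty subset D (up to ``max_denominators`` chromosomes)
    of the candidate autosomes — all autosomes except the chromosome of
    interest and the excluded trisomy candidates — the ratio
    reads(chromosome)/sum(reads over D) is computed per control and the
    subset with the smallest coefficient of variation is kept.  With a
    train/test split the search runs on the train controls and the stored
    statistics (mean, SD, CV, Shapiro P) come from the held-out test
    controls.  Exact CV ties break toward the lexicographically smallest
    chromosome set.
    """
    chromosome = str(chromosome)
    if chromosome not in AUTOSOMES:
        raise NiptScreenError(
            f"NCV chromosome of interest must be an autosome, got "
            f"{chromosome!r}")
    if max_denominators < 1:
        raise NiptScreenError("max_denominators must be >= 1")
    exclude = {str(c) for c in exclude}
    candidates = [c for c in AUTOSOMES
                  if c != chromosome and c not in exclude]
    if not candidates:
        raise NiptScreenError("empty NCV candidate denominator set")
    n_subsets = sum(math.comb(len(candidates), k)
                    for k in range(1, min(max_denominators,
                                          len(candidates)) + 1))
    if n_subsets > max_subsets:
        raise NiptScreenError(
            f"{n_subsets} denominator subsets exceed the cap "
            f"({max_subsets}); lower max_denominators")
    min_size = 5 if use_test_train_set else 3
    if len(group) < min_size:
        raise DegenerateStatisticsError(
            f"NCV template needs >= {min_size} controls, got {len(group)}")

    numerator = np.array(
        [s.chromosome_reads(chromosome) for s in group.samples])
    reads = np.vstack(
        [[s.chromosome_reads(c) for c in candidates] for s in group.samples])

    n = len(group)
    if use_test_train_set:
        train_idx, test_idx = _train_test_split(n, train_fraction, seed)
    else:
        train_idx = test_idx = np.arange(n)

    best = None
    for k in range(1, min(max_denominators, len(candidates)) + 1):
        for subset_idx in combinations(range(len(candidates)), k):
            denom = reads[np.ix_(train_idx, list(subset_idx))].sum(axis=1)
            ratios = numerator[train_idx] / denom
            mean = ratios.mean()
            sd = ratios.std(ddof=1)
            cv = sd / mean
            subset = tuple(candidates[i] for i in subset_idx)
            key = (cv, _subset_sort_key(subset))
            if best is None or key < best[0]:
                best = (key, subset)
    subset = best[1]

    cols = [candidates.index(c) for c in subset]
    eval_ratios = (numerator[test_idx]
                   / reads[np.ix_(test_idx, cols)].sum(axis=1))
    mean = float(eval_ratios.mean())
    sd = float(eval_ratios.std(ddof=1))
    cv = sd / mean
    degenerate = sd == 0
    if degenerate:
        warnings.warn(
            f"NCV ratios for chromosome {chromosome} over {subset} are "
            "exactly constant; template flagged as degenerate", stacklevel=2)
    return NCVTemplate(
        chromosome=chromosome,
        denominators=subset,
        control_ratios=eval_ratios,
        cv=cv,
        control_mean=mean,
        control_sd=sd,
        shapiro_p=_shapiro_p(eval_ratios),
        max_denominators=max_denominators,
        train_test_used=use_test_train_set,
        correction_status=list(group.autosomal_correction_status),
        degenerate=degenerate,
    )


def calculate_ncv_score(sample: BinnedSample,
                        template: NCVTemplate) -> NCVResult:
    """Score a sample against a prepared NCV template."""
    if (template.correction_status
            and sample.autosomal_correction_status != template.correction_status):
        raise StatusMismatchError(
            f"sample correction status {sample.autosomal_correction_status} "
            f"differs from the template's {template.correction_status}")
    if template.control_sd == 0:
        raise DegenerateStatisticsError(
            "NCV template is degenerate (zero control SD)")
    ratio = template.sample_ratio(sample)
    return NCVResult(
        chromosome=template.chromosome,
        ncv_score=(ratio - template.control_mean) / template.control_sd,
        sample_ratio=ratio,
        control_mean=template.control_mean,
        control_sd=template.control_sd,
        shapiro_p=template.shapiro_p,
        n_controls=len(template.control_ratios),
        denominators=template.denominators,
    )


# ---------------------------------------------------------------------------
# Regression-based Z-score
# ---------------------------------------------------------------------------

@dataclass
class RegressionModel:
    """One forward-stepwise model and its score for the test sample."""

    predictors: tuple[tuple[str, str], ...]
    intercept: float
    slopes: np.ndarray
    rbz: float
    vr_sample: float
    cv: float
    cv_type: str
    practical_cv: float
    theoretical_cv: float
    train_cv: float
    test_set_mean: float
    shapiro_p: float

    def to_dict(self) -> dict:
        return {
            "predictors": [list(p) for p in self.predictors],
            "intercept": self.intercept,
            "slopes": list(self.slopes),
            "rbz": self.rbz,
            "vr_sample": self.vr_sample,
            "prediction_statistics": {
                "cv": self.cv,
                "cv_type": self.cv_type,
                "practical_cv": self.practical_cv,
                "theoretical_cv": self.theoretical_cv,
                "train_cv": self.train_cv,
                "test_set_mean": self.test_set_mean,
                "Shapiro_P_value": self.shapiro_p,
            },
        }


@dataclass
class RegressionResult:
    chromosome: str
    models: list[RegressionModel]

    @property
    def rbz_scores(self) -> list[float]:
        return [m.rbz for m in self.models]

    def to_dict(self) -> dict:
        return {"chromosome": self.chromosome,
                "models": [m.to_dict() for m in self.models]}

    def summary(self) -> str:
        lines = [f"Regression-based Z, chromosome {self.chromosome}:"]
        for i, m in enumerate(self.models, 1):
            preds = ", ".join(f"{c}{'+' if s == 'forward' else '-' if s == 'reverse' else ''}"
                              for c, s in m.predictors)
            lines.append(
                f"  model {i}: RBZ {m.rbz:7.3f}  CV {m.cv:.5f} ({m.cv_type})"
                f"  test-set mean {m.test_set_mean:.4f}  "
                f"Shapiro_P {m.shapiro_p:.3f}  predictors [{preds}]")
        return "\n".join(lines)


def _train_test_split(n: int, train_fraction: float,
                      seed_or_rng) -> tuple[np.ndarray, np.ndarray]:
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _forward_stepwise(X: np.ndarray, y: np.ndarray,
                      entities: Sequence[tuple[str, str]],
                      n_predictors: int) -> list[int]:
    """Greedy forward selection minimizing residual sum of squares.

    Ties break toward the lexicographically smallest (chromosome, strand);
    rank-deficient (collinear) candidates are dropped with a warning.
    """
    n = len(y)
    selected: list[int] = []
    remaining = list(range(X.shape[1]))
    design = np.ones((n, 1))
    for _ in range(min(n_predictors, len(remaining))):
        best = None
        for j in remaining:
            cand = np.column_stack([design, X[:, j]])
            coef, residuals, rank, _ = np.linalg.lstsq(cand, y, rcond=None)
            if rank < cand.shape[1]:
                continue
            rss = float(((y - cand @ coef) ** 2).sum())
            key = (rss, (int(entities[j][0]), entities[j][1]))
            if best is None or key < best[0]:
                best = (key, j)
        if best is None:
            warnings.warn("all remaining predictors collinear with the "
                          "design; stopping selection early", stacklevel=2)
            break
        j = best[1]
        selected.append(j)
        remaining.remove(j)
        design = np.column_stack([design, X[:, j]])
    return selected


def perform_regression(
    sample: BinnedSample,
    group: ControlGroup,
    chromosome: str,
    n_models: int = 4,
    n_predictors: int = 4,
    exclude: Iterable[str] = DEFAULT_TRISOMY_CANDIDATES,
    train_fraction: float = 0.6,
    force_practical_cv: bool = False,
    seed: int | None = None,
) -> RegressionResult:
    """Regression-based Z-score with ``n_models`` independent train/test splits.

    Per model: the controls are partitioned into train and test sets; up to
    ``n_predictors`` predictor fractions (autosome x strand, excluding the
    chromosome of interest and the trisomy candidates) are chosen by
    forward-stepwise RSS minimization on the train set; the test-set
    observed/predicted ratios VR give the practical CV and their mean
    (which should be close to one); the reported CV is the larger of the
    practical CV and a counting-noise theoretical CV unless
    ``force_practical_cv``; finally RBZ = (VR_sample - 1)/CV.
    """
    chromosome = str(chromosome)
    _check_statuses(sample, group)
    exclude = {str(c) for c in exclude}
    n = len(group)
    fractions, entities = control_fraction_matrix(group, strand_summed=False)
    keep = [i for i, (c, _s) in enumerate(entities)
            if c != chromosome and c not in exclude]
    if not keep:
        raise NiptScreenError("empty RBZ predictor candidate set")
    X = fractions[:, keep]
    entities = [entities[i] for i in keep]
    y = np.array([chromosomal_fractions(s).chromosome(chromosome)
                  for s in group.samples])

    sample_fv = chromosomal_fractions(sample)
    x_sample = np.array([sample_fv.fractions[e] for e in entities])
    y_sample = sample_fv.chromosome(chromosome)

    rng = np.random.default_rng(seed)
    models = []
    for _ in range(n_models):
        train_idx, test_idx = _train_test_split(n, train_fraction, rng)
        if len(test_idx) < 3:
            raise DegenerateStatisticsError(
                f"RBZ test set has {len(test_idx)} controls; need >= 3")
        sel = _forward_stepwise(X[train_idx], y[train_idx], entities,
                                n_predictors)
        design = np.column_stack([np.ones(len(train_idx)),
                                  X[np.ix_(train_idx, sel)]])
        coef, *_ = np.linalg.lstsq(design, y[train_idx], rcond=None)
        intercept, slopes = float(coef[0]), coef[1:]

        def predict(rows: np.ndarray) -> np.ndarray:
            return intercept + rows[:, sel] @ slopes

        vr_train = y[train_idx] / predict(X[train_idx])
        train_cv = float(vr_train.std(ddof=1) / vr_train.mean())
        vr_test = y[test_idx] / predict(X[test_idx])
        practical_cv = float(vr_test.std(ddof=1) / vr_test.mean())
        test_set_mean = float(vr_test.mean())

        mean_chrom_reads = np.mean(
            [group.samples[i].chromosome_reads(chromosome)
             for i in test_idx])
        mean_pred_reads = np.mean(
            [sum(group.samples[i].chromosome_reads(c, s)
                 for (c, s) in (entities[j] for j in sel))
             for i in test_idx])
        theoretical_cv = math.sqrt(1.0 / mean_chrom_reads
                                   + 1.0 / mean_pred_reads)

        if force_practical_cv or practical_cv >= theoretical_cv:
            cv, cv_type = practical_cv, PRACTICAL_CV
        else:
            cv, cv_type = theoretical_cv, THEORETICAL_CV
        if cv == 0:
            raise DegenerateStatisticsError(
                "RBZ coefficient of variation is zero")

        vr_sample = float(y_sample
                          / (intercept + x_sample[sel] @ slopes))
        models.append(RegressionModel(
            predictors=tuple(entities[j] for j in sel),
            intercept=intercept,
            slopes=slopes,
            rbz=(vr_sample - 1.0) / cv,
            vr_sample=vr_sample,
            cv=cv,
            cv_type=cv_type,
            practical_cv=practical_cv,
            theoretical_cv=theoretical_cv,
            train_cv=train_cv,
            test_set_mean=test_set_mean,
            shapiro_p=_shapiro_p(vr_test),
        ))
    return RegressionResult(chromosome=chromosome, models=models)
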