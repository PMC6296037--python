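"""GC-bias correction and chi-squared variation reduction."""

import numpy as np
import pytest

from niptscreen import (
    BinnedSample,
    GCBinTable,
    as_control_group,
    chi_correct,
    chi_square_bin_statistics,
    gc_correct,
)
from niptscreen.correction import MAX_N_FRACTION, scale_group_to_mean_depth
from niptscreen.errors import (
    DegenerateStatisticsError,
    StatusMismatchError,
)
from niptscreen.samples import AUTOSOMES, CHROMOSOMES, COMBINED

from conftest import SMALL_BINS
from oracles import chi_square_oracle

DF_CUTOFF = 3.5


def flat_sample(value, sample_id="s", bins=SMALL_BINS):
    return BinnedSample(
        sample_id=sample_id, bin_size=50_000,
        counts={c: {COMBINED: np.full(bins[c], float(value))}
                for c in CHROMOSOMES})


def cycling_gc_table(bins=SMALL_BINS, values=(0.40, 0.45, 0.50)):
    """Every GC group is well populated; no gap bins."""
    gc = {c: np.array([values[i % len(values)] for i in range(bins[c])])
          for c in CHROMOSOMES}
    nf = {c: np.zeros(bins[c]) for c in CHROMOSOMES}
    return GCBinTable(bin_size=50_000, gc_fraction=gc, n_fraction=nf)


def biased_sample(gc_table, base=1000.0, beta=0.5, sample_id="b"):
    """Counts deterministically proportional to 1 + beta*(gc - 0.5)."""
    counts = {}
    for c in CHROMOSOMES:
        gc = gc_table.gc_fraction[c]
        w = base * (1 + beta * (gc - 0.5))
        w = np.where(gc_table.n_fraction[c] > MAX_N_FRACTION, 0.0, w)
        counts[c] = {COMBINED: w}
    return BinnedSample(sample_id=sample_id, bin_size=50_000, counts=counts)


# ---------------------------------------------------------------------------
# GC correction
# ---------------------------------------------------------------------------

def test_flat_counts_unchanged_by_bin_method():
    """With no GC dependence every group weight is 1."""
    gc_table = cycling_gc_table()
    sample = flat_sample(100.0)
    out = gc_correct(sample, gc_table, method="bin")
    for c in AUTOSOMES:
        np.testing.assert_allclose(out.counts[c][COMBINED],
                                   sample.counts[c][COMBINED], rtol=1e-12)
    assert out.autosomal_correction_status == ["Uncorrected", "GC Corrected"]
    assert out.sex_correction_status == ["Uncorrected"]
    # X/Y untouched without include_XY
    np.testing.assert_array_equal(out.counts["X"][COMBINED],
                                  sample.counts["X"][COMBINED])


def test_bin_method_equalizes_gc_group_means(small_gc_table):
    """After weighted-bin correction every retained GC group's mean equals
    the global mean of usable bins."""
    sample = biased_sample(small_gc_table)
    out = gc_correct(sample, small_gc_table, method="bin")
    gc = np.concatenate([small_gc_table.gc_fraction[c] for c in AUTOSOMES])
    nf = np.concatenate([small_gc_table.n_fraction[c] for c in AUTOSOMES])
    raw = np.concatenate([sample.counts[c][COMBINED] for c in AUTOSOMES])
    corr = np.concatenate([out.counts[c][COMBINED] for c in AUTOSOMES])
    usable = nf <= MAX_N_FRACTION
    global_mean = raw[usable].mean()
    groups = np.round(gc[usable] / 0.01).astype(int)
    for g in np.unique(groups):
        in_g = usable.copy()
        in_g[usable] = groups == g
        if (corr[in_g] > 0).any():      # retained group
            assert corr[in_g].mean() == pytest.approx(global_mean,
                                                      rel=1e-6)


def test_loess_flattens_deterministic_gc_response(small_gc_table):
    """On noise-free counts exactly linear in GC, the locally weighted fit
    reproduces the response and the corrected counts are constant (equal to
    the usable-bin mean)."""
    sample = biased_sample(small_gc_table)
    out = gc_correct(sample, small_gc_table, method="loess")
    gc = np.concatenate([small_gc_table.gc_fraction[c] for c in AUTOSOMES])
    nf = np.concatenate([small_gc_table.n_fraction[c] for c in AUTOSOMES])
    raw = np.concatenate([sample.counts[c][COMBINED] for c in AUTOSOMES])
    corr = np.concatenate([out.counts[c][COMBINED] for c in AUTOSOMES])
    usable = nf <= MAX_N_FRACTION
    assert abs(np.corrcoef(raw[usable], gc[usable])[0, 1]) > 0.9
    np.testing.assert_allclose(corr[usable], raw[usable].mean(), rtol=1e-9)
    assert out.autosomal_correction_status[-1] == "LOESS GC Corrected"


def test_loess_removes_gc_count_correlation_on_noisy_counts(small_gc_table):
    """On Poisson-noisy GC-biased counts the residual count-GC correlation
    drops to near zero."""
    rng = np.random.default_rng(4)
    sample = biased_sample(small_gc_table)
    for c in AUTOSOMES:
        sample.counts[c][COMBINED] = rng.poisson(
            sample.counts[c][COMBINED]).astype(float)
    out = gc_correct(sample, small_gc_table, method="loess")
    gc = np.concatenate([small_gc_table.gc_fraction[c] for c in AUTOSOMES])
    nf = np.concatenate([small_gc_table.n_fraction[c] for c in AUTOSOMES])
    raw = np.concatenate([sample.counts[c][COMBINED] for c in AUTOSOMES])
    corr = np.concatenate([out.counts[c][COMBINED] for c in AUTOSOMES])
    usable = nf <= MAX_N_FRACTION
    assert abs(np.corrcoef(raw[usable], gc[usable])[0, 1]) > 0.5
    assert abs(np.corrcoef(corr[usable], gc[usable])[0, 1]) < 0.02


def test_gc_group_order_preserved_within_groups(small_gc_table,
                                                small_group):
    """Within one GC group all bins share a weight, so the count order of
    a sample's bins in that group is preserved."""
    sample = small_group.samples[0]
    out = gc_correct(sample, small_gc_table, method="bin")
    gc = small_gc_table.gc_fraction["1"]
    raw = sample.counts["1"][COMBINED if not sample.strand_separated
                             else "forward"]
    corr = out.counts["1"][COMBINED if not sample.strand_separated
                           else "forward"]
    groups = np.round(gc / 0.01).astype(int)
    for g in np.unique(groups):
        mask = (groups == g) & (corr > 0)
        if mask.sum() > 1:
            assert (np.argsort(raw[mask], kind="stable")
                    == np.argsort(corr[mask], kind="stable")).all()


def test_gc_correct_rejects_already_corrected(small_gc_table, small_group):
    once = gc_correct(small_group.samples[0], small_gc_table)
    with pytest.raises(StatusMismatchError):
        gc_correct(once, small_gc_table)


# ---------------------------------------------------------------------------
# Chi-squared variation reduction
# ---------------------------------------------------------------------------

def _constructed_group(n=20):
    """Flat controls except one sample with an inflated chr1 bin, depth-
    compensated on chr2 so scaling is the identity."""
    samples = [flat_sample(100.0, f"c{i}") for i in range(n)]
    outlier = samples[-1]
    outlier.counts["1"][COMBINED][0] = 400.0
    outlier.counts["2"][COMBINED][:3] = 0.0
    return as_control_group(samples)


def test_identical_controls_flag_nothing():
    group = as_control_group([flat_sample(50.0, f"c{i}") for i in range(5)])
    sample = flat_sample(50.0, "t")
    corrected, corrected_group, report = chi_correct(sample, group)
    assert report.flagged == set()
    assert report.degrees_of_freedom == 4
    for c in AUTOSOMES:
        np.testing.assert_array_equal(corrected.counts[c][COMBINED],
                                      sample.counts[c][COMBINED])
    assert (corrected.autosomal_correction_status
            == ["Uncorrected", "Chi Corrected"])
    scores = np.concatenate(
        [report.normalized_score[(c, COMBINED)] for c in AUTOSOMES])
    assert (scores[~np.isnan(scores)] < 0).all()


def test_chi_statistics_match_brute_force_oracle():
    group = _constructed_group()
    sample = flat_sample(100.0, "t")
    corrected, corrected_group, report = chi_correct(sample, group,
                                                     cutoff_sd=DF_CUTOFF)
    scaled = scale_group_to_mean_depth(group)
    df = report.degrees_of_freedom
    for chrom in ("1", "2", "3"):
        matrix = np.vstack([s.counts[chrom][COMBINED]
                            for s in scaled.samples])
        for b in range(matrix.shape[1]):
            chi_oracle, df_oracle = chi_square_oracle(matrix[:, b].tolist())
            got = report.chi_statistic[(chrom, COMBINED)][b]
            assert df == df_oracle
            if chi_oracle is None:
                assert np.isnan(got)
                continue
            assert got == pytest.approx(chi_oracle, rel=1e-12)
            score = (chi_oracle - df) / np.sqrt(2 * df)
            assert (((chrom, COMBINED, b) in report.flagged)
                    == (score > DF_CUTOFF))
            if score > DF_CUTOFF:
                assert corrected.counts[chrom][COMBINED][b] == pytest.approx(
                    sample.counts[chrom][COMBINED][b] / (chi_oracle / df),
                    rel=1e-12)


def test_chi_self_consistency_and_unflagged_untouched():
    """Dividing flagged bins by chi2/df rescales their statistic to exactly
    df; unflagged bins of the scaled controls are bit-identical."""
    group = _constructed_group()
    sample = flat_sample(100.0, "t")
    _, corrected_group, report = chi_correct(sample, group)
    assert report.flagged            # the construction must flag something
    scaled = scale_group_to_mean_depth(group)
    df = report.degrees_of_freedom
    for chrom in AUTOSOMES:
        matrix = np.vstack([s.counts[chrom][COMBINED]
                            for s in corrected_group.samples])
        chi, _ = chi_square_bin_statistics(matrix)
        before = np.vstack([s.counts[chrom][COMBINED]
                            for s in scaled.samples])
        for b in range(matrix.shape[1]):
            if (chrom, COMBINED, b) in report.flagged:
                assert chi[b] == pytest.approx(df, rel=1e-9)
            else:
                np.testing.assert_array_equal(matrix[:, b], before[:, b])


def test_chi_preserves_cross_sample_order(small_group):
    """Flagged-bin divisors are shared by all samples, so which sample has
    the larger count in any bin never changes."""
    sample = small_group.samples[0].copy("t")
    _, corrected_group, report = chi_correct(sample, small_group)
    scaled = scale_group_to_mean_depth(small_group)
    strand = small_group.strands[0]
    for chrom in ("1", "21"):
        before = np.vstack([s.counts[chrom][strand]
                            for s in scaled.samples])
        after = np.vstack([s.counts[chrom][strand]
                           for s in corrected_group.samples])
        assert (np.argsort(before, axis=0, kind="stable")
                == np.argsort(after, axis=0, kind="stable")).all()


def test_chi_correct_errors(small_group, small_gc_table):
    sample = small_group.samples[0].copy("t")
    gc_sample = gc_correct(sample, small_gc_table)
    with pytest.raises(StatusMismatchError):
        chi_correct(gc_sample, small_group)    # status mismatch
    tiny = as_control_group(small_group.samples[:2])
    with pytest.raises(DegenerateStatisticsError):
        chi_correct(sample, tiny)              # too few controls
    once, once_group, _ = chi_correct(sample, small_group)
    with pytest.raises(StatusMismatchError):
        chi_correct(once, once_group)          # chi twice
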