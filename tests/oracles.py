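"""Independent brute-force oracles, deliberately written with plain Python
loops and stdlib statistics so they share no code path with the package."""

from __future__ import annotations

import statistics
from itertools import combinations


def mean(xs):
    return sum(xs) / len(xs)


def sample_sd(xs):
    return statistics.stdev(xs)


def z_score_oracle(sample_value, control_values):
    m = mean(control_values)
    s = sample_sd(control_values)
    return (sample_value - m) / s


def chromosomal_fraction_oracle(counts, chromosomes):
    """counts: chrom -> strand -> list; returns (chrom, strand) -> fraction."""
    autosomes = [str(i) for i in range(1, 23)]
    total = 0.0
    for c in autosomes:
        for vec in counts[c].values():
            total += sum(float(x) for x in vec)
    return {
        (c, s): sum(float(x) for x in vec) / total
        for c in chromosomes
        for s, vec in counts[c].items()
    }


def chi_square_oracle(columns):
    """columns: list of per-sample values for one bin -> (chi2, df)."""
    n = len(columns)
    e = mean(columns)
    if e == 0:
        return None, n - 1
    chi = sum((x - e) ** 2 / e for x in columns)
    return chi, n - 1


def match_ss_oracle(fractions_a, fractions_b):
    """Sum of squared differences between two fraction vectors (dicts)."""
    return sum((fractions_a[k] - fractions_b[k]) ** 2 for k in fractions_a)


def ncv_exhaustive_oracle(numerators, candidate_reads, candidates,
                          max_denominators):
    """Enumerate every denominator subset; return (best subset, best cv).

    numerators: per-control reads on the chromosome of interest;
    candidate_reads: per-control dict candidate -> reads.
    Ties break toward the lexicographically smallest chromosome set.
    """
    best = None
    for k in range(1, min(max_denominators, len(candidates)) + 1):
        for subset in combinations(candidates, k):
            ratios = [
                num / sum(reads[c] for c in subset)
                for num, reads in zip(numerators, candidate_reads)
            ]
            cv = sample_sd(ratios) / mean(ratios)
            key = (cv, tuple(sorted(int(c) for c in subset)))
            if best is None or key < best[0]:
                best = (key, subset)
    return best[1], best[0][0]


def _ols_rss(design_cols, y):
    """RSS of least squares with intercept, via statsmodels (independent
    of the numpy.linalg.lstsq route used by the implementation)."""
    import numpy as np
    import statsmodels.api as sm

    X = sm.add_constant(np.column_stack(design_cols)) if design_cols \
        else np.ones((len(y), 1))
    fit = sm.OLS(y, X).fit()
    return float(fit.ssr)


def stepwise_oracle(X, y, entities, n_predictors):
    """Greedy forward selection recomputing RSS at every step."""
    selected = []
    remaining = list(range(X.shape[1]))
    for _ in range(min(n_predictors, len(remaining))):
        scored = []
        for j in remaining:
            cols = [X[:, k] for k in selected] + [X[:, j]]
            rss = _ols_rss(cols, y)
            scored.append(((rss, (int(entities[j][0]), entities[j][1])), j))
        scored.sort()
        j = scored[0][1]
        selected.append(j)
        remaining.remove(j)
    return selected


def loo_z_oracle(values):
    """Leave-one-out Z for each element of a list."""
    out = []
    for i, x in enumerate(values):
        rest = values[:i] + values[i + 1:]
        out.append((x - mean(rest)) / sample_sd(rest))
    return out
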