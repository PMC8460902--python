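"""Statistical analysis of cohort descriptors and classifier performance.

Continuous group contrasts use an unpaired t-test, switching to the
Wilcoxon rank-sum test when either group fails a Shapiro-Wilk normality
screen; proportions use the chi-squared test, switching to Fisher's exact
test when an expected cell count drops below 5 (2x2 tables).  Classifier
accuracy distributions are compared by a Kruskal-Wallis test with
Tukey-Kramer post-hoc comparisons on mean ranks; the reduced-vs-full
contrast uses a Wilcoxon rank-sum test per algorithm and metric.
Correlations are Pearson, or Spearman under non-normality.  All tests use
alpha = 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as ss

__all__ = [
    "ALPHA", "is_normal", "compare_groups", "proportion_test",
    "kruskal_with_posthoc", "tukey_kramer_ranks", "reduced_vs_full_tests",
    "correlation", "correlation_table",
]

ALPHA = 0.05


def is_normal(x, alpha: float = ALPHA) -> bool:
    """Shapiro-Wilk screen; degenerate samples are treated as non-normal."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    return ss.shapiro(x).pvalue >= alpha


def compare_groups(a, b):
    """Two-group contrast for a continuous parameter: ('t', p) or
    ('wilcoxon', p) depending on the normality screen."""
    if is_normal(a) and is_normal(b):
        return "t", float(ss.ttest_ind(a, b).pvalue)
    return "wilcoxon", float(ss.ranksums(a, b).pvalue)


def proportion_test(table):
    """Chi-squared test on a contingency table, or Fisher's exact test when
    any expected count is below 5 (2x2 tables)."""
    table = np.asarray(table, dtype=float)
    expected = ss.contingency.expected_freq(table)
    if (expected < 5).any() and table.shape == (2, 2):
        return "fisher", float(ss.fisher_exact(table).pvalue)
    return "chi2", float(ss.chi2_contingency(table).pvalue)


def tukey_kramer_ranks(samples: dict) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons on mean ranks (the classical
    post-hoc after a Kruskal-Wallis test): the studentized-range statistic
    q = |R_i - R_j| / sqrt(N(N+1)/12 * (1/n_i + 1/n_j) / 2) referenced to
    the studentized range distribution with infinite error df."""
    names = list(samples)
    pooled = np.concatenate([np.asarray(samples[n], float) for n in names])
    ranks = ss.rankdata(pooled)
    N = len(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for n in names:
        k = len(samples[n])
        mean_ranks[n] = ranks[start:start + k].mean()
        sizes[n] = k
        start += k
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            se = np.sqrt(N * (N + 1) / 12.0 * (1.0 / sizes[a] + 1.0 / sizes[b]) / 2.0)
            q = abs(mean_ranks[a] - mean_ranks[b]) / se
            p = float(ss.studentized_range.sf(q, len(names), np.inf))
            rows.append({"a": a, "b": b, "q": q, "pvalue": p})
    return pd.DataFrame(rows)


def kruskal_with_posthoc(samples: dict):
    """Overall Kruskal-Wallis p-value across the per-algorithm accuracy
    distributions, with Tukey-Kramer post-hoc comparisons run only when the
    overall test is significant."""
    groups = [np.asarray(v, float) for v in samples.values()]
    if all(np.array_equal(groups[0], g) for g in groups[1:]):
        return 1.0, None
    p = float(ss.kruskal(*groups).pvalue)
    posthoc = tukey_kramer_ranks(samples) if p < ALPHA else None
    return p, posthoc


def reduced_vs_full_tests(result) -> pd.DataFrame:
    """Wilcoxon rank-sum p-value for reduced vs full sensitivity and
    specificity, per selected algorithm."""
    rows = []
    algs = sorted({alg for alg, _ in result.sensitivity})
    for alg in algs:
        for metric, store in (("sensitivity", result.sensitivity),
                              ("specificity", result.specificity)):
            p = float(ss.ranksums(store[(alg, "reduced")],
                                  store[(alg, "full")]).pvalue)
            rows.append({"algorithm": alg, "metric": metric, "pvalue": p})
    return pd.DataFrame(rows)


def correlation(x, y):
    """Pearson (both margins normal) or Spearman correlation with its
    two-sided significance; degenerate inputs give (nan, nan, 'undefined')."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), "undefined"
    if is_normal(x) and is_normal(y):
        r = ss.pearsonr(x, y)
        return float(r.statistic), float(r.pvalue), "pearson"
    r = ss.spearmanr(x, y)
    return float(r.statistic), float(r.pvalue), "spearman"


def correlation_table(df: pd.DataFrame, rows, cols) -> pd.DataFrame:
    """Pairwise correlation matrix (geometrical x biomechanical style
    report) with method and significance per cell."""
    out = []
    for a in rows:
        for b in cols:
            r, p, method = correlation(df[a], df[b])
            out.append({"row": a, "col": b, "r": r, "pvalue": p,
                        "method": method, "significant": bool(p < ALPHA)
                        if np.isfinite(p) else False})
    return pd.DataFrame(out)
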