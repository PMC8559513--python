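"""Two-group tests used throughout the pipeline.

* Fisher's exact test (probability-mass two-sided convention) for per-gene
  mutation-frequency comparisons;
* Pearson chi-square for clinical balance tables — Yates-corrected with
  truncation at zero for 2x2 tables, uncorrected for larger tables (this
  is the combination that reproduces published baseline-characteristics
  tables in this literature);
* Wilcoxon rank-sum for continuous variables (TMB, age, lnIC50), exact
  when feasible and tie-free, otherwise a tie-corrected normal
  approximation with continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .burden import MUT_HIGH, MUT_LOW, GroupAssignment
from .io import MutationTable


@dataclass
class TestResult:
    statistic: float
    p: float
    method: str
    effect: float | None = None  # odds ratio (2x2) or rank-biserial (Wilcoxon)
    effect_name: str = ""


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The two-sided p sums hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's (within a small relative tolerance).  A zero margin gives
    p = 1 by convention.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("fisher_exact needs a non-negative 2x2 table")
    if t.sum() == 0:
        raise ValueError("empty table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("zero margin in 2x2 table; p = 1 by convention")
        return TestResult(np.nan, 1.0, "fisher_exact", None, "odds_ratio")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel()
    sample_or = (a * d) / (b * c) if b * c > 0 else np.inf
    return TestResult(float(sample_or), float(p), "fisher_exact",
                      float(sample_or), "odds_ratio")


def chi2_test(table, correction: str = "auto") -> TestResult:
    """Pearson chi-square on an r x c table.

    correction='yates' (2x2 only) uses sum(max(0, |O-E|-0.5)^2 / E): the
    continuity correction truncated at zero, so a table whose cells all
    sit within 0.5 of expectation yields statistic 0 and p = 1.
    correction='auto' applies Yates to 2x2 tables and none otherwise.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0):
        raise ValueError("chi2_test needs a non-negative 2-D table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero row/column margin in contingency table")
    if correction == "auto":
        correction = "yates" if t.shape == (2, 2) else "none"
    if correction == "yates" and t.shape != (2, 2):
        raise ValueError("Yates correction applies to 2x2 tables only")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    dev = np.abs(t - expected)
    if correction == "yates":
        dev = np.maximum(0.0, dev - 0.5)
    stat = float((dev**2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return TestResult(stat, p, f"chi2_{correction}")


def wilcoxon_ranksum(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    mode='auto' uses the exact permutation null when n_x * n_y <= 400 and
    there are no ties, else the normal approximation with tie-corrected
    variance and continuity correction.  Effect size is the rank-biserial
    correlation r = 2*U/(n_x*n_y) - 1 (positive when x tends larger).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical in both samples; p = 1")
        return TestResult(len(x) * len(y) / 2, 1.0, "wilcoxon_degenerate",
                          0.0, "rank_biserial")
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        mode = "exact" if (len(x) * len(y) <= 400 and not has_ties) else "normal"
    if mode == "exact" and has_ties:
        mode = "normal"
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=(method == "asymptotic"))
    u = float(res.statistic)
    rb = 2 * u / (len(x) * len(y)) - 1
    return TestResult(u, float(min(res.pvalue, 1.0)), f"wilcoxon_{mode}",
                      float(rb), "rank_biserial")


# significance-star tiers used in mutation-profile figures
STAR_TIERS = [(0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*")]


def _stars(p: float) -> str:
    for cut, mark in STAR_TIERS:
        if p < cut:
            return mark
    return ""


def compare_top_genes(
    mutations: MutationTable,
    groups: GroupAssignment,
    top_k: int = 20,
    extra_genes=(),
    extra_min_freq: float = 0.05,
) -> pd.DataFrame:
    """Per-gene mutation-frequency comparison between mut-high and mut-low.

    Ranks genes by overall mutated-sample frequency, keeps the top_k (ties
    at the boundary are all kept, alphabetically ordered), appends any
    ``extra_genes`` (e.g. pathway members) whose overall frequency exceeds
    ``extra_min_freq``, and tests each gene's mutated/not x high/low 2x2
    with Fisher's exact test.  Star annotations follow the usual
    0.05/0.01/0.001/0.0001 tiers.
    """
    if len(mutations) == 0:
        raise ValueError("empty mutation table")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    samples = list(groups.labels.index)
    n = len(samples)
    rec = mutations.records
    rec = rec[rec["sample_id"].isin(samples)]
    mutated = rec.drop_duplicates(["sample_id", "gene"])
    freq = mutated.groupby("gene")["sample_id"].size() / n
    ranked = freq.sort_values(ascending=False, kind="stable")
    if len(ranked) > top_k:
        cutoff = ranked.iloc[top_k - 1]
        keep = sorted(ranked[ranked >= cutoff].index)
    else:
        keep = sorted(ranked.index)
    extras = sorted(
        g for g in set(extra_genes) - set(keep)
        if freq.get(g, 0.0) > extra_min_freq
    )
    high = set(groups.labels[groups.labels == MUT_HIGH].index)
    low = set(groups.labels[groups.labels == MUT_LOW].index)
    rows = []
    for gene in [*sorted(keep, key=lambda g: (-freq[g], g)), *extras]:
        carriers = set(mutated.loc[mutated["gene"] == gene, "sample_id"])
        a = len(carriers & high)
        b = len(high) - a
        c = len(carriers & low)
        d = len(low) - c
        if b == 0 and d == 0:  # mutated in every sample of both groups
            res = TestResult(np.inf, 1.0, "fisher_exact", None, "odds_ratio")
        else:
            res = fisher_exact([[a, b], [c, d]])
        rows.append(
            {
                "gene": gene,
                "freq_overall": float(freq.get(gene, 0.0)),
                "freq_high": a / len(high) if high else np.nan,
                "freq_low": c / len(low) if low else np.nan,
                "p": res.p,
                "stars": _stars(res.p),
                "in_top_k": gene not in extras,
            }
        )
    return pd.DataFrame(rows)


def clinical_balance_table(clinical, groups: GroupAssignment,
                           continuous=(), categorical=()) -> pd.DataFrame:
    """Baseline-characteristics balance tests between mut-high and mut-low.

    Continuous covariates use the Wilcoxon rank-sum test; categorical
    covariates a chi-square (Yates for 2x2, uncorrected otherwise).
    """
    labels = groups.labels.reindex(clinical.data.index)
    hi = labels == MUT_HIGH
    rows = []
    for name in continuous:
        v = clinical.data[name].astype(float)
        res = wilcoxon_ranksum(v[hi].dropna(), v[~hi].dropna())
        rows.append({"covariate": name, "test": res.method, "p": res.p})
    for name in categorical:
        v = clinical.data[name].dropna()
        tab = pd.crosstab(v, labels.reindex(v.index))
        res = chi2_test(tab.to_numpy())
        rows.append({"covariate": name, "test": res.method, "p": res.p})
    return pd.DataFrame(rows)
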