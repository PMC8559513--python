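"""Expression-level mechanism stages: empirical-Bayes moderated-t
differential expression, preranked GSEA, single-sample gene-set scoring,
differential pathway expression, and pathway-score survival analysis.

Moderated t
-----------
Per-gene two-group linear models share information through an
inverse-chi-square prior on the residual variances: the posterior
variance is s2_tilde = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g), with the prior
degrees of freedom d0 and prior variance s0^2 estimated by moment
matching on log s_g^2 (digamma/trigamma matching).  The moderated t uses
d0 + d_g degrees of freedom; as d0 -> 0 it reduces to the ordinary
two-sample t.

GSEA / single-sample scoring
----------------------------
Preranked GSEA uses the weighted Kolmogorov-Smirnov running sum (hit
increments proportional to |score|^weight normalised over the set, miss
decrements uniform over the complement) with a seeded gene-label
permutation null.  Per-sample scoring is the rank-ECDF (ssGSEA-style)
integral, which is deterministic and invariant to monotone transforms of
a sample's expression values; the kernel-density variant is deliberately
not implemented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .burden import MUT_HIGH, MUT_LOW, GroupAssignment, dichotomize
from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection
from .survival import CoxResult, KMCurve, cox_fit, km_fit_groups


# ---------------------------------------------------------------------------
# moderated-t differential expression


@dataclass
class DGEResult:
    table: pd.DataFrame          # per gene: logFC, t, p, q, df_total, flag
    d0: float                    # prior degrees of freedom (may be inf)
    s0_sq: float                 # prior variance

    def de_genes(self, p_cut: float = 0.05, lfc_cut: float = 1.0) -> pd.DataFrame:
        """Differentially expressed calls at p < p_cut and |log2 FC| > lfc_cut
        (|FC| > 2 on the natural scale)."""
        t = self.table
        return t[(t["p"] < p_cut) & (t["logFC"].abs() > lfc_cut)]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match an inverse-chi-square prior (d0, s0^2) to sample
    variances s2 on df residual degrees of freedom (Smyth-style)."""
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2)
    if evar > 0:
        d0 = 2 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return float(d0), float(s0_sq)


def dge_moderated_t(
    expr: ExpressionMatrix,
    groups: GroupAssignment,
    prior: tuple[float, float] | None = None,
) -> DGEResult:
    """Empirical-Bayes moderated two-group differential expression.

    logFC is mut_high minus mut_low on the (log) expression scale.
    ``prior`` fixes (d0, s0_sq) instead of estimating them; d0 = 0 recovers
    the ordinary two-sample t, d0 = inf a z-test against the prior variance.
    """
    labels = groups.labels.reindex(expr.samples)
    hi = (labels == MUT_HIGH).to_numpy()
    lo = (labels == MUT_LOW).to_numpy()
    n1, n2 = int(hi.sum()), int(lo.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group for DGE")
    X = expr.values.to_numpy(float)
    m1 = X[:, hi].mean(axis=1)
    m2 = X[:, lo].mean(axis=1)
    logfc = m1 - m2
    ss = ((X[:, hi] - m1[:, None]) ** 2).sum(axis=1) + (
        (X[:, lo] - m2[:, None]) ** 2
    ).sum(axis=1)
    df_resid = n1 + n2 - 2
    s2 = ss / df_resid
    d0, s0_sq = prior if prior is not None else fit_variance_prior(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    denom = np.sqrt(s2_post * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(denom > 0, logfc / np.where(denom > 0, denom, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2 * stats.t.sf(np.abs(tstat), df_total)
    # zero within-group variance in both groups: declared untestable
    flat = s2 == 0
    tstat = np.where(flat, 0.0, tstat)
    p = np.where(flat, 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "t": tstat,
            "p": p,
            "q": q,
            "df_total": df_total,
            "flag_zero_variance": flat,
        },
        index=expr.values.index,
    )
    return DGEResult(table, d0, s0_sq)


# ---------------------------------------------------------------------------
# preranked GSEA


@dataclass
class EnrichmentResult:
    table: pd.DataFrame               # per set: ES, NES, p, size
    leading_edge: dict[str, list]     # set -> genes up to the ES peak
    n_perm: int
    weight: float
    seed: int | None


def _running_es(order_scores: np.ndarray, hit: np.ndarray, weight: float):
    """Weighted KS running sum over a ranked list; returns (ES, peak_idx)."""
    w = np.abs(order_scores) ** weight
    w_hit = np.where(hit, w, 0.0)
    nr = w_hit.sum()
    if nr == 0:  # all-zero scores inside the set: fall back to unweighted
        w_hit = hit.astype(float)
        nr = w_hit.sum()
    n_miss = len(hit) - int(hit.sum())
    p_hit = np.cumsum(w_hit) / nr
    p_miss = np.cumsum(~hit) / n_miss
    # ES is bounded by [-1, 1] exactly; guard against cumsum round-off
    run = np.clip(p_hit - p_miss, -1.0, 1.0)
    peak = int(np.argmax(np.abs(run)))
    return float(run[peak]), peak, run


def gsea_preranked(
    ranking: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int | None = None,
    min_size: int = 5,
    max_size: int = 500,
) -> EnrichmentResult:
    """Preranked GSEA with a seeded gene-label permutation null.

    ``ranking`` maps gene -> score (e.g. logFC); the list is sorted
    descending.  p = (1 + #{|ES_perm| >= |ES|}) / (1 + n_perm); NES is the
    ES divided by the mean |permuted ES| of the same sign.
    """
    from .io import normalize_symbol

    ranking = ranking.rename(index=normalize_symbol)
    if ranking.index.has_duplicates:
        raise ValueError("ranking contains duplicate genes")
    # descending by score, ties broken by stable gene-label order
    ranking = ranking.iloc[np.argsort(ranking.index, kind="stable")]
    ranking = ranking.sort_values(ascending=False, kind="stable")
    genes = ranking.index.to_numpy()
    scores = ranking.to_numpy(float)
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    rows, leading = [], {}
    for name in sets.names():
        members = [g for g in sets[name] if g in gene_pos]
        t = len(members)
        if t < min_size or t > max_size:
            continue
        if t == n:
            raise ValueError(f"gene set {name!r} covers the whole ranking")
        hit = np.zeros(n, bool)
        hit[[gene_pos[g] for g in members]] = True
        es, peak, _ = _running_es(scores, hit, weight)
        # permutation null: random sets of the same size
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            ph = np.zeros(n, bool)
            ph[rng.choice(n, size=t, replace=False)] = True
            perm_es[b], _, _ = _running_es(scores, ph, weight)
        p = (1 + np.sum(np.abs(perm_es) >= abs(es))) / (1 + n_perm)
        same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        denom = np.mean(np.abs(same_sign)) if len(same_sign) else np.mean(np.abs(perm_es))
        nes = es / denom if denom > 0 else np.nan
        if es >= 0:
            le = [g for g in genes[: peak + 1] if hit[gene_pos[g]]]
        else:
            le = [g for g in genes[peak:] if hit[gene_pos[g]]]
        rows.append({"set_name": name, "ES": es, "NES": nes, "p": p, "size": t})
        leading[name] = le
    table = pd.DataFrame(rows, columns=["set_name", "ES", "NES", "p", "size"])
    return EnrichmentResult(table, leading, n_perm, weight, seed)


# ---------------------------------------------------------------------------
# single-sample (ssGSEA-style) scoring


@dataclass
class SampleScoreMatrix:
    scores: pd.DataFrame          # gene_sets x samples
    method: str = "ssgsea_rank_ecdf"
    alpha: float = 0.25
    normalized: bool = True

    def row(self, set_name: str) -> pd.Series:
        return self.scores.loc[set_name]


def ssgsea_score(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
    min_overlap: int = 2,
) -> SampleScoreMatrix:
    """Rank-ECDF single-sample enrichment scores (genes ranked within each
    sample; genes absent from the expression matrix are ignored).

    For each sample, genes are ranked by expression (rank N = highest);
    walking the list in decreasing-rank order, the score is the summed
    difference between the |rank|^alpha-weighted in-set ECDF and the
    uniform out-of-set ECDF.  With normalize=True all scores are divided
    by the (max - min) over the whole matrix.
    """
    X = expr.values
    n_genes, n_samples = X.shape
    # ranks: 1 = lowest expression ... N = highest, per sample
    ranks = X.rank(axis=0, method="first").to_numpy()
    gene_index = X.index
    raw = {}
    for name in sets.names():
        members = np.asarray(gene_index.isin(sets[name]))
        if members.sum() < min_overlap:
            warnings.warn(
                f"gene set {name!r}: fewer than {min_overlap} expressed members; skipped"
            )
            continue
        col_scores = np.empty(n_samples)
        n_out = n_genes - int(members.sum())
        for j in range(n_samples):
            order = np.argsort(-ranks[:, j], kind="stable")
            inset = members[order]
            r = ranks[order, j]
            w = np.where(inset, np.abs(r) ** alpha, 0.0)
            p_in = np.cumsum(w) / w.sum()
            p_out = np.cumsum(~inset) / n_out
            col_scores[j] = float(np.sum(p_in - p_out))
        raw[name] = col_scores
    if not raw:
        raise ValueError("no gene set had sufficient overlap with the expression matrix")
    scores = pd.DataFrame(raw, index=X.columns).T
    if normalize:
        spread = float(scores.to_numpy().max() - scores.to_numpy().min())
        if spread > 0:
            scores = scores / spread
    return SampleScoreMatrix(scores, alpha=alpha, normalized=normalize)


# ---------------------------------------------------------------------------
# pathway scores downstream


def pathway_score_survival(
    scores: SampleScoreMatrix,
    clinical: ClinicalTable,
    set_name: str,
    ties: str = "efron",
) -> tuple[dict[str, KMCurve], CoxResult]:
    """Median-split a pathway score and relate the split to survival.

    The split is strict (score > median = high), mirroring the mutation
    grouping; the high group is coded 1 in the Cox model, so HR < 1 means
    a higher pathway score is protective.
    """
    if set_name not in scores.scores.index:
        raise KeyError(f"no scored set named {set_name!r}")
    col = scores.row(set_name).reindex(clinical.samples).dropna()
    sub = clinical.subset(col.index)
    grp = dichotomize(col, set_name)
    if grp.degenerate:
        raise ValueError(f"degenerate score split for {set_name!r}")
    labels = grp.labels.map({MUT_HIGH: "score_high", MUT_LOW: "score_low"})
    sub2 = sub.with_covariate("score_group", (labels == "score_high").astype(int),
                              kind="binary")
    curves = km_fit_groups(sub.data["time"], sub.data["event"], labels)
    cox = cox_fit(sub2, ["score_group"], ties=ties)[0]
    return curves, cox


def diff_pathway_expression(
    scores: SampleScoreMatrix,
    groups: GroupAssignment,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-set two-sample t-test of pathway scores between mut-high and
    mut-low, BH-adjusted.  ``equal_var=False`` switches to Welch."""
    labels = groups.labels.reindex(scores.scores.columns)
    hi = (labels == MUT_HIGH).to_numpy()
    lo = (labels == MUT_LOW).to_numpy()
    if hi.sum() < 2 or lo.sum() < 2:
        raise ValueError("need >= 2 samples per group")
    M = scores.scores.to_numpy(float)
    res = stats.ttest_ind(M[:, hi], M[:, lo], axis=1, equal_var=equal_var)
    out = pd.DataFrame(
        {
            "mean_high": M[:, hi].mean(axis=1),
            "mean_low": M[:, lo].mean(axis=1),
            "t": res.statistic,
            "p": res.pvalue,
        },
        index=scores.scores.index,
    )
    out["t"] = out["t"].fillna(0.0)
    out["p"] = out["p"].fillna(1.0)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
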