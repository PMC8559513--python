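import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathburden.burden import GroupAssignment, dichotomize
from pathburden.enrichment import (
    dge_moderated_t,
    diff_pathway_expression,
    fit_variance_prior,
    gsea_preranked,
    pathway_score_survival,
    ssgsea_score,
)
from pathburden.io import ClinicalTable, ExpressionMatrix, GeneSetCollection
from pathburden.synth import SynthConfig, generate_cohort


def _expr(values, genes=None, samples=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def _grp(n_high, n_low):
    labels = pd.Series(
        ["mut_high"] * n_high + ["mut_low"] * n_low,
        index=[f"s{i}" for i in range(n_high + n_low)],
    )
    return GroupAssignment(labels, 0.0, "set")


class TestModeratedT:
    def test_identical_group_means_zero(self):
        rng = np.random.default_rng(0)
        block = rng.normal(0, 1, (50, 4))
        X = np.hstack([block, block])  # identical values in both groups
        res = dge_moderated_t(_expr(X), _grp(4, 4))
        assert np.allclose(res.table["logFC"], 0)
        assert np.allclose(res.table["t"], 0)

    def test_zero_prior_df_recovers_ordinary_t(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (30, 10))
        res = dge_moderated_t(_expr(X), _grp(5, 5), prior=(0.0, 1.0))
        ref = stats.ttest_ind(X[:, :5], X[:, 5:], axis=1)
        assert np.allclose(res.table["t"], ref.statistic, atol=1e-6)
        assert np.allclose(res.table["p"], ref.pvalue, atol=1e-6)

    def test_variance_prior_recovery(self):
        """Moment-matching recovers a known inverse-chi-square prior."""
        rng = np.random.default_rng(2)
        d0_true, s0_true, df = 6.0, 1.5, 10
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, 5000)
        s2 = sigma2 * rng.chisquare(df, 5000) / df
        d0, s0 = fit_variance_prior(s2, df)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s0 == pytest.approx(s0_true, rel=0.05)

    def test_bh_adjusted_p_at_least_raw(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (100, 12))
        res = dge_moderated_t(_expr(X), _grp(6, 6))
        assert (res.table["q"] >= res.table["p"] - 1e-12).all()

    def test_flat_gene_flagged(self):
        X = np.vstack([np.ones(8), np.random.default_rng(4).normal(0, 1, (5, 8))])
        res = dge_moderated_t(_expr(X), _grp(4, 4))
        row = res.table.iloc[0]
        assert row["flag_zero_variance"] and row["t"] == 0 and row["p"] == 1

    def test_de_recall_and_fdr_on_planted_signal(self):
        rng = np.random.default_rng(5)
        G, n = 2000, 10
        X = rng.normal(0, 1, (G, 2 * n))
        de = np.arange(100)
        X[np.ix_(de, np.arange(n))] += 2.0  # logFC = 2 in mut_high
        res = dge_moderated_t(_expr(X), _grp(n, n))
        called = res.de_genes(p_cut=0.05, lfc_cut=1.0)
        called_bh = res.table[(res.table["q"] < 0.05) & (res.table["logFC"].abs() > 1)]
        de_names = {f"G{i}" for i in de}  # symbols are normalized upper-case
        recall = len(set(called.index) & de_names) / 100
        fp = len(set(called_bh.index) - de_names)
        fdr = fp / max(1, len(called_bh))
        assert recall >= 0.8
        assert fdr <= 0.1

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_limma_reference(self, tmp_path):
        """Independent oracle: R limma on the same matrix agrees to 1e-8."""
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (120, 12)) * rng.lognormal(0, 0.4, 120)[:, None]
        X[:8, :6] += 1.2
        expr = _expr(X)
        expr.values.to_csv(tmp_path / "expr.tsv", sep="\t")
        script = tmp_path / "cmp.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.table("{tmp_path}/expr.tsv", header=TRUE, '
            'row.names=1, sep="\\t"))\n'
            'grp <- factor(c(rep("high",6), rep("low",6)), levels=c("low","high"))\n'
            'fit <- eBayes(lmFit(x, model.matrix(~grp)))\n'
            'out <- topTable(fit, coef=2, number=Inf, sort.by="none")\n'
            f'write.table(data.frame(t=out$t, p=out$P.Value), "{tmp_path}/out.tsv", '
            'sep="\\t", row.names=FALSE, quote=FALSE)\n'
        )
        proc = subprocess.run(["Rscript", str(script)], capture_output=True)
        if proc.returncode != 0:
            pytest.skip(f"limma unavailable: {proc.stderr[-200:]}")
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        res = dge_moderated_t(expr, _grp(6, 6))
        assert np.allclose(res.table["t"].to_numpy(), ref["t"].to_numpy(), atol=1e-8)
        assert np.allclose(res.table["p"].to_numpy(), ref["p"].to_numpy(), atol=1e-8)


class TestGseaPreranked:
    def _ranking(self, n=10):
        return pd.Series(np.linspace(3, -3, n), index=[f"g{i}" for i in range(n)])

    def test_top_concentrated_set_es_one(self):
        ranking = self._ranking(50)
        sets = GeneSetCollection({"TOP": {f"g{i}" for i in range(5)}})
        res = gsea_preranked(ranking, sets, n_perm=50, seed=0)
        assert res.table["ES"].iloc[0] == pytest.approx(1.0)

    def test_classic_ks_hand_computed(self):
        # 10 genes, set at ranked positions {1, 4, 8}, weight 0:
        # peak after position 4: P_hit 2/3, P_miss 2/7 -> ES = 8/21
        ranking = self._ranking(10)
        sets = GeneSetCollection({"S": {"g0", "g3", "g7"}})
        res = gsea_preranked(ranking, sets, n_perm=10, weight=0.0, seed=0,
                             min_size=1)
        assert res.table["ES"].iloc[0] == pytest.approx(8 / 21)

    def test_reversed_ranking_negates_classic_es(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=40)
        ranking = pd.Series(scores, index=[f"g{i}" for i in range(40)])
        sets = GeneSetCollection({"S": {f"g{i}" for i in range(0, 40, 7)}})
        fwd = gsea_preranked(ranking, sets, n_perm=10, weight=0.0, seed=0)
        rev = gsea_preranked(-ranking, sets, n_perm=10, weight=0.0, seed=0)
        assert fwd.table["ES"].iloc[0] == pytest.approx(-rev.table["ES"].iloc[0])

    def test_es_bounded_and_p_bounded(self):
        rng = np.random.default_rng(8)
        ranking = pd.Series(rng.normal(size=60), index=[f"g{i}" for i in range(60)])
        sets = GeneSetCollection(
            {f"S{k}": set(rng.choice([f"g{i}" for i in range(60)], 8, replace=False))
             for k in range(10)}
        )
        res = gsea_preranked(ranking, sets, n_perm=20, seed=1)
        assert ((res.table["ES"] >= -1) & (res.table["ES"] <= 1)).all()
        assert ((res.table["p"] >= 1 / 21) & (res.table["p"] <= 1)).all()

    def test_full_coverage_set_fatal(self):
        ranking = self._ranking(6)
        sets = GeneSetCollection({"ALL": {f"g{i}" for i in range(6)}})
        with pytest.raises(ValueError, match="covers the whole ranking"):
            gsea_preranked(ranking, sets, n_perm=10, min_size=1)

    def test_fixed_seed_reproducible(self):
        ranking = self._ranking(30)
        sets = GeneSetCollection({"S": {f"g{i}" for i in range(3, 12)}})
        a = gsea_preranked(ranking, sets, n_perm=100, seed=42)
        b = gsea_preranked(ranking, sets, n_perm=100, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_duplicate_genes_fatal(self):
        r = pd.Series([1.0, 2.0], index=["g1", "g1"])
        with pytest.raises(ValueError, match="duplicate"):
            gsea_preranked(r, GeneSetCollection({"S": {"g1"}}), n_perm=10)


class TestSsgsea:
    def test_hand_computed_toy(self):
        # 5 genes, one sample, expression A>B>C>D>E, set {A, C}, alpha=.25:
        # walk A,B,C,D,E with in-set weights 5^.25 and 3^.25
        X = _expr([[5.0], [4.0], [3.0], [2.0], [1.0]],
                  genes=list("ABCDE"), samples=["s0"])
        sets = GeneSetCollection({"S": {"A", "C"}})
        res = ssgsea_score(X, sets, alpha=0.25, normalize=False)
        wa, wc = 5**0.25, 3**0.25
        w = wa + wc
        expected = (wa / w) + (wa / w - 1 / 3) + (1 - 1 / 3) + (1 - 2 / 3) + 0
        assert res.scores.loc["S", "s0"] == pytest.approx(expected)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (40, 6))
        sets = GeneSetCollection({"S": {f"g{i}" for i in range(4, 14)}})
        a = ssgsea_score(_expr(X), sets, normalize=False)
        b = ssgsea_score(_expr(np.exp(X) + 7), sets, normalize=False)
        pd.testing.assert_frame_equal(a.scores, b.scores)

    def test_absent_gene_in_set_no_effect(self):
        rng = np.random.default_rng(10)
        X = rng.normal(0, 1, (20, 5))
        s1 = GeneSetCollection({"S": {f"g{i}" for i in range(5)}})
        s2 = GeneSetCollection({"S": {f"g{i}" for i in range(5)} | {"ABSENT"}})
        pd.testing.assert_frame_equal(
            ssgsea_score(_expr(X), s1).scores, ssgsea_score(_expr(X), s2).scores
        )

    def test_top_ranked_set_scores_maximal(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, (30, 8))
        X[:5, 0] = 100.0  # sample 0 puts the set genes at the top
        sets = GeneSetCollection({"S": {f"g{i}" for i in range(5)}})
        res = ssgsea_score(_expr(X), sets)
        assert res.scores.loc["S"].idxmax() == "s0"

    def test_insufficient_overlap_skipped(self):
        rng = np.random.default_rng(12)
        X = rng.normal(0, 1, (10, 3))
        sets = GeneSetCollection({"S": {"g0"}, "OK": {"g1", "g2", "g3"}})
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = ssgsea_score(_expr(X), sets)
        assert list(res.scores.index) == ["OK"]


class TestPathwayScoreDownstream:
    def test_diff_pathway_expression_null_and_shape(self):
        rng = np.random.default_rng(13)
        scores = pd.DataFrame(rng.normal(0, 1, (4, 20)),
                              index=[f"P{i}" for i in range(4)],
                              columns=[f"s{i}" for i in range(20)])
        from pathburden.enrichment import SampleScoreMatrix

        out = diff_pathway_expression(SampleScoreMatrix(scores), _grp(10, 10))
        assert len(out) == 4
        assert (out["p"] > 0.001).all()  # no planted effect

    def test_diff_pathway_planted_shift_detected(self):
        rng = np.random.default_rng(14)
        hits = 0
        for rep in range(10):
            scores = rng.normal(0, 1, (1, 40))
            scores[0, :20] += 1.5  # 1.5-SD shift in mut_high
            from pathburden.enrichment import SampleScoreMatrix

            m = SampleScoreMatrix(pd.DataFrame(
                scores, index=["P"], columns=[f"s{i}" for i in range(40)]))
            out = diff_pathway_expression(m, _grp(20, 20))
            hits += out["p"].iloc[0] < 0.01
        assert hits >= 9

    def test_constant_score_column_fatal(self):
        from pathburden.enrichment import SampleScoreMatrix

        scores = pd.DataFrame(np.ones((1, 12)), index=["P"],
                              columns=[f"s{i}" for i in range(12)])
        clin = ClinicalTable(pd.DataFrame(
            {"time": np.arange(1.0, 13.0), "event": [1] * 12},
            index=pd.Index([f"s{i}" for i in range(12)], name="sample_id")))
        with pytest.raises(ValueError, match="degenerate"):
            pathway_score_survival(SampleScoreMatrix(scores), clin, "P")

    def test_planted_protective_score_direction(self):
        """Samples with high causal-pathway expression are the mut-high
        samples, whose hazard is scaled by exp(beta) < 1, so the score
        split should estimate HR < 1 in most cohorts."""
        hits = 0
        for rep in range(8):
            cohort = generate_cohort(
                SynthConfig(n_samples=60, n_expr_genes=300, expr_delta=2.0,
                            beta=float(np.log(0.3)), seed=300 + rep)
            )
            scores = ssgsea_score(cohort.expression, cohort.gene_sets)
            _, cox = pathway_score_survival(
                scores, cohort.clinical, cohort.truth.causal_set_name
            )
            hits += cox.hr < 1
        assert hits >= 7
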