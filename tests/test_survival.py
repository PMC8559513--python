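import numpy as np
import pandas as pd
import pytest

from pathburden.io import ClinicalTable
from pathburden.survival import (
    cox_fit,
    cox_multivariate,
    efron_loglik,
    km_fit,
    logrank_test,
    newton_cox,
)


def _clin(times, events, **covs):
    data = pd.DataFrame({"time": times, "event": events, **{k: v[0] for k, v in covs.items()}},
                        index=pd.Index([f"P{i}" for i in range(len(times))],
                                       name="sample_id"))
    kinds = {k: v[1] for k, v in covs.items()}
    return ClinicalTable(data, covariate_kinds=kinds)


class TestKaplanMeier:
    def test_no_censoring_steps(self):
        km = km_fit([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        assert np.allclose(km.survival, [0.8, 0.6, 0.4, 0.2, 0.0])
        assert km.median == 3

    def test_all_censored_flat_median_not_reached(self):
        km = km_fit([1, 2, 3], [0, 0, 0])
        assert len(km.times) == 0 and km.median is None

    def test_censored_mix_product_limit(self):
        # events at 1, 3, 5; censored at 2 and 4
        km = km_fit([1, 2, 3, 4, 5], [1, 0, 1, 0, 1])
        assert km.survival_at(1) == pytest.approx(0.8)
        assert km.survival_at(3) == pytest.approx(0.8 * (1 - 1 / 3))
        assert km.survival_at(5) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(5, 40).round(2) + 0.1
        km = km_fit(t, np.ones(40, int))
        for q in [np.min(t), np.median(t), np.max(t)]:
            assert km.survival_at(q) == pytest.approx(np.mean(t > q))

    def test_empty_group_fatal(self):
        with pytest.raises(ValueError):
            km_fit([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 1, 0, 1, 1, 1, 0]
        g = list("aaaabbbb")
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_toy_instance_matches_direct_oe(self):
        # 6 samples, all events: group a at {1,2,3}, group b at {4,5,6}
        t = [1, 2, 3, 4, 5, 6]
        e = [1] * 6
        g = list("aaabbb")
        # direct O-E over the event times:
        # t=1: n=6,n_a=3,d=1 -> E=.5,V=.25 ; t=2: n=5,n_a=2 -> E=.4,V=.24
        # t=3: n=4,n_a=1 -> E=.25,V=.1875 ; later times have n_a=0
        oe = (1 - 0.5) + (1 - 0.4) + (1 - 0.25)
        var = 0.25 + 0.24 + 0.1875
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(oe**2 / var)

    def test_separated_groups_significant(self):
        t = list(range(1, 11)) + [50 + i for i in range(10)]
        e = [1] * 10 + [0] * 10
        g = ["early"] * 10 + ["none"] * 10
        _, p = logrank_test(t, e, g)
        assert p < 0.05

    def test_single_group_fatal(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([1, 2], [1, 1], ["a", "a"])


class TestCoxFit:
    def _random_instance(self, rng):
        n = int(rng.integers(8, 13))
        x = rng.integers(0, 2, n).astype(float)
        t = np.round(rng.exponential(10, n) * np.exp(-0.5 * x), 1) + 0.1
        e = rng.integers(0, 2, n)
        if e.sum() == 0:
            e[0] = 1
        return t, e, x

    def test_matches_grid_oracle(self):
        """Newton solution equals brute-force maximization of the Efron
        partial likelihood on a 1e-4 grid over [-5, 5]."""
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 5:
            t, e, x = self._random_instance(rng)
            beta, _, _, diag = newton_cox(t, e, x[:, None])
            if abs(beta[0]) > 5 or not diag["converged"]:
                continue
            coarse = np.arange(-5, 5.001, 0.01)
            ll = [efron_loglik([b], t, e, x[:, None]) for b in coarse]
            b0 = coarse[int(np.argmax(ll))]
            fine = np.arange(b0 - 0.02, b0 + 0.02, 1e-4)
            llf = [efron_loglik([b], t, e, x[:, None]) for b in fine]
            assert abs(beta[0] - fine[int(np.argmax(llf))]) < 1e-4
            checked += 1

    def test_group_flip_negates_beta(self):
        rng = np.random.default_rng(2)
        t, e, x = self._random_instance(rng)
        b1, _, _, _ = newton_cox(t, e, x[:, None])
        b2, _, _, _ = newton_cox(t, e, (1 - x)[:, None])
        assert b1[0] == pytest.approx(-b2[0], abs=1e-8)

    def test_time_scaling_invariance(self):
        rng = np.random.default_rng(3)
        t, e, x = self._random_instance(rng)
        b1, _, _, _ = newton_cox(t, e, x[:, None])
        b2, _, _, _ = newton_cox(t * 7.3, e, x[:, None])
        assert b1[0] == pytest.approx(b2[0], abs=1e-8)

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(4)
        n = 15
        t = rng.permutation(np.arange(1.0, n + 1))  # unique times
        e = rng.integers(0, 2, n)
        e[:2] = 1
        x = rng.normal(size=n)
        be, _, _, _ = newton_cox(t, e, x[:, None], ties="efron")
        bb, _, _, _ = newton_cox(t, e, x[:, None], ties="breslow")
        assert be[0] == pytest.approx(bb[0], abs=1e-10)

    def test_wald_ci_and_p_agree(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            t, e, x = self._random_instance(rng)
            clin = _clin(t, e, g=(x, "binary"))
            res = cox_fit(clin, ["g"])[0]
            lo, hi = res.ci95
            excludes_one = not (lo <= 1.0 <= hi)
            assert excludes_one == (res.p < 0.05)

    def test_null_covariate_beta_near_zero(self):
        rng = np.random.default_rng(8)
        n = 300
        t = rng.exponential(10, n) + 0.01
        e = np.ones(n, int)
        x = rng.permutation(np.repeat([0.0, 1.0], n // 2))
        b, se, _, _ = newton_cox(t, e, x[:, None])
        assert abs(b[0]) < 3 * se[0]

    def test_perfect_separation_flagged_and_capped(self):
        t = np.array([1, 2, 3, 4, 10, 11, 12, 13.0])
        e = np.ones(8, int)
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0.0])
        b, _, _, diag = newton_cox(t, e, x[:, None])
        assert diag["flag"] == "monotone_likelihood"
        assert abs(b[0]) <= 15

    def test_lifelines_cross_check(self):
        """Independent implementation agreement on a moderate cohort."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(9)
        n = 80
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(10, n) * np.exp(-0.7 * x) + 0.01
        e = (rng.uniform(size=n) < 0.7).astype(int)
        e[:2] = 1
        b, se, _, _ = newton_cox(t, e, x[:, None])
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e"
        )
        assert b[0] == pytest.approx(cph.params_.iloc[0], abs=1e-3)
        assert se[0] == pytest.approx(cph.standard_errors_.iloc[0], rel=1e-3)


class TestCoxMultivariate:
    def test_single_term_equals_univariate(self):
        rng = np.random.default_rng(10)
        n = 30
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(8, n) + 0.1
        e = rng.integers(0, 2, n)
        e[0] = 1
        clin = _clin(t, e, g=(x, "binary"))
        uni = cox_fit(clin, ["g"])[0]
        multi = cox_multivariate(clin, ["g"])[0]
        assert uni.beta == pytest.approx(multi.beta, abs=1e-12)

    def test_null_term_beta_near_zero_joint(self):
        rng = np.random.default_rng(12)
        n = 400
        causal = rng.integers(0, 2, n).astype(float)
        noise = rng.normal(size=n)
        t = rng.exponential(10, n) * np.exp(-0.8 * causal) + 0.01
        e = np.ones(n, int)
        clin = _clin(t, e, causal=(causal, "binary"), noise=(noise, "continuous"))
        res = {r.term: r for r in cox_multivariate(clin, ["causal", "noise"])}
        assert abs(res["noise"].beta) < 3 * res["noise"].se
        # times shrunk by exp(-0.8) for causal=1 => hazard ratio exp(+0.8)
        assert res["causal"].beta > 0.4

    def test_rank_deficiency_names_collinear_terms(self):
        rng = np.random.default_rng(13)
        n = 20
        x = rng.normal(size=n)
        t = rng.exponential(5, n) + 0.1
        e = np.ones(n, int)
        clin = _clin(t, e, a=(x, "continuous"), b=(2 * x, "continuous"))
        with pytest.raises(ValueError, match="rank deficient"):
            cox_multivariate(clin, ["a", "b"])

    def test_confounded_group_adjusted_ci_covers_one(self):
        """Group correlated with stage but only stage causal: the adjusted
        group CI should cover HR=1 in most replicates."""
        rng = np.random.default_rng(14)
        cover = 0
        reps = 60
        for _ in range(reps):
            n = 120
            stage = rng.integers(0, 2, n).astype(float)
            group = np.where(rng.uniform(size=n) < 0.7, stage, 1 - stage)
            t = rng.exponential(10, n) * np.exp(-1.0 * stage) + 0.01
            e = (rng.uniform(size=n) < 0.8).astype(int)
            if e.sum() < 5:
                continue
            clin = _clin(t, e, group=(group, "binary"), stage=(stage, "binary"))
            res = {r.term: r for r in cox_multivariate(clin, ["group", "stage"])}
            lo, hi = res["group"].ci95
            cover += lo <= 1.0 <= hi
        assert cover / reps >= 0.90
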