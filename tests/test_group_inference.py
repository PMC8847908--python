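"""Covariate-adjusted ANCOVA/MANCOVA per node, BH correction, node screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import netpheno as nph
from netpheno.group_inference import (
    ancova_node,
    build_design,
    fdr_bh,
    mancova_node,
    screen_nodes,
)


def make_phenotypes(rng, n, balanced=True):
    group = np.repeat([0, 1], n // 2) if balanced else (rng.random(n) < 0.5).astype(int)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": group,
            "age": rng.normal(30, 8, n),
            "sex": rng.integers(0, 2, n),
            "motion": rng.lognormal(-2, 0.5, n),
            "site": rng.integers(0, 3, n),
        }
    )


class TestAncova:
    def test_no_covariates_equals_squared_t(self, rng):
        phen = make_phenotypes(rng, 40)
        y = rng.standard_normal(40) + 0.5 * phen["group"].to_numpy()
        F, p, _, _ = ancova_node(y, phen, covariates=())
        t, p_t = stats.ttest_ind(
            y[phen["group"] == 1], y[phen["group"] == 0], equal_var=True
        )
        assert F == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(p_t, rel=1e-8)

    def test_matches_glm_by_hand(self, rng):
        """Residual-sum-of-squares F from explicit design matrices."""
        phen = make_phenotypes(rng, 40)
        y = rng.standard_normal(40)
        covs = ("age", "motion")
        F, p, eta, _ = ancova_node(y, phen, covariates=covs)
        X_full, X_red, _ = build_design(phen, covs)
        sse = lambda X: np.sum((y - X @ np.linalg.pinv(X) @ y) ** 2)
        df_e = 40 - X_full.shape[1]
        F_hand = (sse(X_red) - sse(X_full)) / (sse(X_full) / df_e)
        assert F == pytest.approx(F_hand, rel=1e-10)
        assert eta == pytest.approx((sse(X_red) - sse(X_full)) / sse(X_red), rel=1e-10)

    def test_matches_statsmodels(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        phen = make_phenotypes(rng, 60)
        y = rng.standard_normal(60) + 0.3 * phen["group"]
        F, p, _, _ = ancova_node(y, phen, covariates=("age", "motion"))
        df = phen.assign(
            y=y,
            age_z=(phen.age - phen.age.mean()) / phen.age.std(),
            mot_z=(phen.motion - phen.motion.mean()) / phen.motion.std(),
        )
        fit = smf.ols("y ~ group + age_z + mot_z", data=df).fit()
        tab = anova_lm(fit, typ=3)
        assert F == pytest.approx(tab.loc["group", "F"], rel=1e-8)
        assert p == pytest.approx(tab.loc["group", "PR(>F)"], rel=1e-6)

    def test_constant_metric_flagged_nan(self, rng):
        phen = make_phenotypes(rng, 30)
        F, p, eta, d = ancova_node(np.ones(30), phen, covariates=("age",))
        assert np.isnan(F) and np.isnan(p) and d == "·"

    def test_direction_codes(self, rng):
        phen = make_phenotypes(rng, 60)
        g = phen["group"].to_numpy()
        *_, d_up = ancova_node(g * 2.0 + rng.normal(0, 0.1, 60), phen, covariates=())
        *_, d_dn = ancova_node(-g * 2.0 + rng.normal(0, 0.1, 60), phen, covariates=())
        assert d_up == "E" and d_dn == "W"

    def test_collinear_design_raises(self, rng):
        phen = make_phenotypes(rng, 30)
        phen["age"] = phen["group"] * 1.0  # perfectly collinear with group
        with pytest.raises(ValueError, match="collinear"):
            ancova_node(rng.standard_normal(30), phen, covariates=("age",))


class TestMancova:
    def test_collinear_dependents_raise(self, rng):
        phen = make_phenotypes(rng, 40)
        y = rng.standard_normal(40)
        with pytest.raises(np.linalg.LinAlgError):
            mancova_node(y, 2.0 * y, phen, covariates=("age",))

    def test_matches_statsmodels_pillai(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        phen = make_phenotypes(rng, 50)
        y1 = rng.standard_normal(50) + 0.4 * phen["group"]
        y2 = rng.standard_normal(50)
        F, p, V = mancova_node(y1, y2, phen, covariates=("age", "motion"))
        df = phen.assign(
            y1=y1,
            y2=y2,
            age_z=(phen.age - phen.age.mean()) / phen.age.std(),
            mot_z=(phen.motion - phen.motion.mean()) / phen.motion.std(),
        )
        mv = MANOVA.from_formula("y1 + y2 ~ group + age_z + mot_z", data=df)
        tab = mv.mv_test().results["group"]["stat"]
        assert V == pytest.approx(tab.loc["Pillai's trace", "Value"], rel=1e-8)
        assert F == pytest.approx(tab.loc["Pillai's trace", "F Value"], rel=1e-8)
        assert p == pytest.approx(tab.loc["Pillai's trace", "Pr > F"], rel=1e-6)

    def test_f_increases_with_effect_size(self, rng):
        """Planted group shifts of growing size give growing F."""
        phen = make_phenotypes(rng, 80)
        g = phen["group"].to_numpy().astype(float)
        noise1, noise2 = rng.standard_normal(80), rng.standard_normal(80)
        Fs = [
            mancova_node(noise1 + d * g, noise2 + d * g, phen, covariates=("age",))[0]
            for d in (0.0, 0.8, 1.6)
        ]
        assert Fs[0] < Fs[1] < Fs[2]


class TestFdrBh:
    def test_hand_step_up(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        rej, adj = fdr_bh(p, 0.05)
        assert rej.all()  # p_(i) <= i*q/m for every i

    def test_all_ones_none_rejected(self):
        rej, _ = fdr_bh(np.ones(10), 0.05)
        assert not rej.any()

    def test_single_p(self):
        rej, adj = fdr_bh(np.array([0.04]), 0.05)
        assert rej[0] and adj[0] == pytest.approx(0.04)

    def test_empty(self):
        rej, adj = fdr_bh(np.array([]), 0.05)
        assert rej.size == 0 and adj.size == 0

    def test_order_invariance(self, rng):
        p = rng.random(50)
        perm = rng.permutation(50)
        _, adj = fdr_bh(p)
        _, adj_p = fdr_bh(p[perm])
        assert np.allclose(adj[perm], adj_p)

    def test_adjusted_monotone_in_rank(self, rng):
        p = rng.random(30)
        _, adj = fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestScreenNodes:
    def test_recovers_planted_nodes(self, small_cohort, small_cohort_metrics):
        deg, eff, labels = small_cohort_metrics
        res = screen_nodes(deg, eff, small_cohort.phenotypes, labels)
        planted = {labels[i] for i in (2, 5, 9)}
        # strong delta=1.0 effect: all planted nodes among the consistent set
        assert planted <= set(res.consistent_nodes)
        sub = res.table[res.table.roi.isin(planted)]
        assert (sub.direction_deg == "E").all()

    def test_table_contract(self, small_cohort, small_cohort_metrics):
        deg, eff, labels = small_cohort_metrics
        res = screen_nodes(deg, eff, small_cohort.phenotypes, labels)
        t = res.table
        assert len(t) == len(labels)
        for col in ("p_mancova", "q_mancova", "p_deg", "q_deg", "p_eff", "q_eff"):
            assert ((t[col] >= 0) & (t[col] <= 1)).all()
        # BH never lowers a p-value
        assert (t.q_mancova >= t.p_mancova - 1e-12).all()

    def test_unadjusted_equals_bruteforce_two_group_F(self, rng):
        phen = make_phenotypes(rng, 50)
        deg = rng.standard_normal((50, 6))
        eff = rng.standard_normal((50, 6))
        res = screen_nodes(deg, eff, phen, [f"r{i}" for i in range(6)], covariates=())
        for j in range(6):
            F, *_ = ancova_node(deg[:, j], phen, covariates=())
            assert res.table.F_deg[j] == pytest.approx(F, rel=1e-8)

    def test_joint_ancova_family_option(self, rng):
        phen = make_phenotypes(rng, 50)
        deg = rng.standard_normal((50, 6))
        eff = rng.standard_normal((50, 6))
        labels = [f"r{i}" for i in range(6)]
        res3 = screen_nodes(deg, eff, phen, labels, fdr_families="three")
        resj = screen_nodes(deg, eff, phen, labels, fdr_families="joint-ancova")
        assert np.allclose(res3.table.p_deg, resj.table.p_deg)
        _, adj_joint = fdr_bh(np.concatenate([res3.table.p_deg, res3.table.p_eff]))
        assert np.allclose(resj.table.q_deg, adj_joint[:6])
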