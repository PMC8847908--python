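"""Composites, cross-validated prediction/classification, permutation nulls, CPM."""

import numpy as np
import pandas as pd
import pytest

from netpheno.predictive_modeling import (
    build_composites,
    cpm_predict,
    cross_sample_classify,
    kfold_classify,
    kfold_predict_continuous,
    metric_table,
    permutation_calibrate,
    stability_select,
    unify_directions,
)


def toy_metrics(rng, n=80, R=6):
    deg = rng.standard_normal((n, R))
    eff = rng.standard_normal((n, R))
    return metric_table(deg, eff, [f"r{i}" for i in range(R)])


class TestComposites:
    def test_unify_flips_only_negative(self, rng):
        M = toy_metrics(rng)
        out = unify_directions(M, {"deg:r0": -1, "deg:r1": 1})
        assert np.array_equal(out["deg:r0"], -M["deg:r0"])
        assert np.array_equal(out["deg:r1"], M["deg:r1"])

    def test_unify_flip_negates_correlation(self, rng):
        M = toy_metrics(rng)
        y = rng.standard_normal(len(M))
        r0 = np.corrcoef(M["deg:r0"], y)[0, 1]
        out = unify_directions(M, {"deg:r0": -1})
        assert np.corrcoef(out["deg:r0"], y)[0, 1] == pytest.approx(-r0)

    def test_unify_rejects_zero_sign(self, rng):
        with pytest.raises(ValueError):
            unify_directions(toy_metrics(rng), {"deg:r0": 0})

    def test_single_member_equals_metric(self, rng):
        M = toy_metrics(rng)
        comp = build_composites(M, ["deg:r2"], ["eff:r3"])
        assert np.array_equal(comp.t_deg, M["deg:r2"])
        assert np.array_equal(comp.t_eg, M["eff:r3"])

    def test_mean_oracle(self, rng):
        M = toy_metrics(rng)
        comp = build_composites(M, ["deg:r0", "deg:r1", "deg:r2"], ["eff:r0"])
        assert np.allclose(
            comp.t_deg, M[["deg:r0", "deg:r1", "deg:r2"]].mean(axis=1)
        )

    def test_missing_member_raises(self, rng):
        with pytest.raises(ValueError):
            build_composites(toy_metrics(rng), ["deg:zzz"], [])


class TestKfoldContinuous:
    def test_perfect_signal(self, rng):
        X = rng.standard_normal((100, 2))
        y = 3.0 * X[:, 0] - 1.5 * X[:, 1] + 2.0
        out = kfold_predict_continuous(X, y, k=10, seed=0)
        assert out.estimate > 0.999

    def test_every_subject_predicted_once(self, rng):
        X = rng.standard_normal((50, 2))
        y = rng.standard_normal(50)
        out = kfold_predict_continuous(X, y, k=10, seed=1)
        assert np.isfinite(out.predicted).all()
        assert np.bincount(out.fold_assignments).sum() == 50

    def test_null_bias_negative_median(self):
        """CV on pure noise biases r(predicted, observed) below zero."""
        local = np.random.default_rng(811)
        rs = []
        for s in range(30):
            X = local.standard_normal((300, 2))
            y = local.standard_normal(300)
            rs.append(kfold_predict_continuous(X, y, k=10, seed=s).estimate)
        assert np.median(rs) <= 0
        assert np.max(np.abs(rs)) < 0.25

    def test_reproducible(self, rng):
        X = rng.standard_normal((60, 2))
        y = rng.standard_normal(60)
        a = kfold_predict_continuous(X, y, k=10, seed=7)
        b = kfold_predict_continuous(X, y, k=10, seed=7)
        assert np.array_equal(a.predicted, b.predicted)
        assert a.estimate == b.estimate


class TestKfoldClassify:
    def test_separated_groups_perfect(self, rng):
        n = 60
        labels = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 2)) + 10.0 * labels[:, None]
        out = kfold_classify(X, labels, k=10, seed=0)
        assert out.estimate == 1.0
        assert out.per_group_accuracy == {"western": 1.0, "eastern": 1.0}

    def test_label_coding_per_group(self, rng):
        """Per-group accuracies map 0 -> western, 1 -> eastern."""
        n = 80
        labels = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 2)) + 3.0 * labels[:, None]
        out = kfold_classify(X, labels, k=10, seed=3)
        pred = out.predicted
        assert out.per_group_accuracy["western"] == pytest.approx(
            np.mean(pred[labels == 0] == 0)
        )
        assert out.per_group_accuracy["eastern"] == pytest.approx(
            np.mean(pred[labels == 1] == 1)
        )

    def test_requires_two_classes(self, rng):
        with pytest.raises(ValueError):
            kfold_classify(rng.standard_normal((30, 2)), np.zeros(30), k=5)


class TestPermutationCalibrate:
    def test_bookkeeping(self, rng):
        y = rng.standard_normal(60)
        proc = lambda y_perm, s: float(np.mean(y_perm[:10]))
        cal = permutation_calibrate(proc, y, observed_estimate=0.0, n_perm=100, seed=1)
        assert cal["null_distribution"].size == 100
        ordered = np.sort(cal["null_distribution"])
        # positions round(0.025*100)=3 and round(0.975*100)=98 (1-based)
        assert cal["ci95"] == (ordered[2], ordered[97])

    def test_positions_at_1000(self, rng):
        y = rng.standard_normal(50)
        proc = lambda y_perm, s: float(y_perm[0])
        cal = permutation_calibrate(proc, y, 0.0, n_perm=1000, seed=2)
        ordered = np.sort(cal["null_distribution"])
        assert cal["ci95"] == (ordered[24], ordered[974])

    def test_observed_inside_null_not_significant(self, rng):
        y = rng.standard_normal(50)
        proc = lambda y_perm, s: float(np.mean(y_perm))
        cal = permutation_calibrate(proc, y, float(np.mean(y)), n_perm=200, seed=3)
        assert not cal["significant"]
        assert 0 < cal["p_perm"] <= 1

    def test_too_few_permutations_raise(self, rng):
        with pytest.raises(ValueError):
            permutation_calibrate(lambda a, b: 0.0, rng.standard_normal(10), 0.0, n_perm=30)

    def test_exchangeability_of_prepermuted_outcome(self, rng):
        """A fixed relabeling before calibration leaves the null unchanged."""
        from scipy import stats

        X = rng.standard_normal((80, 2))
        y = rng.standard_normal(80)
        proc = lambda y_perm, s: kfold_predict_continuous(X, y_perm, k=5, seed=s).estimate
        a = permutation_calibrate(proc, y, 0.0, n_perm=120, seed=4)
        y_shuf = y[rng.permutation(80)]
        b = permutation_calibrate(proc, y_shuf, 0.0, n_perm=120, seed=5)
        assert stats.ks_2samp(a["null_distribution"], b["null_distribution"]).pvalue > 0.01


class TestCpm:
    def test_strong_metrics_selected_every_fold(self, rng):
        n, R = 120, 8
        deg = rng.standard_normal((n, R))
        eff = rng.standard_normal((n, R))
        y = deg[:, 1] - deg[:, 3] + 0.3 * rng.standard_normal(n)
        M = metric_table(deg, eff, [f"r{i}" for i in range(R)])
        out, fold_sets = cpm_predict(M, y, k=10, seed=0)
        stable = stability_select(fold_sets, min_count=10)
        assert {"deg:r1", "deg:r3"} <= stable
        assert out.estimate > 0.5

    def test_null_selection_rate_near_alpha(self, rng):
        n, R = 200, 20
        M = metric_table(
            rng.standard_normal((n, R)), rng.standard_normal((n, R)),
            [f"r{i}" for i in range(R)],
        )
        y = rng.standard_normal(n)
        _, fold_sets = cpm_predict(M, y, k=10, alpha=0.05, seed=1)
        rate = np.mean([len(s) for s in fold_sets]) / (2 * R)
        assert rate < 0.15  # expected ~ alpha

    def test_empty_selection_falls_back_to_mean(self, rng):
        n = 60
        M = metric_table(
            rng.standard_normal((n, 2)), rng.standard_normal((n, 2)), ["a", "b"]
        )
        y = rng.standard_normal(n)
        out, _ = cpm_predict(M, y, k=10, alpha=1e-9, seed=2)
        assert np.isfinite(out.predicted).all()
        assert out.extra["warnings"]


class TestStabilitySelect:
    def test_counting(self):
        sets = [{"a", "b"}] * 10 + []
        assert stability_select(sets, 10) == {"a", "b"}
        sets = [{"a"}] * 9 + [set()]
        assert stability_select(sets, 10) == set()

    def test_bruteforce_count_oracle(self, rng):
        names = [f"m{i}" for i in range(6)]
        sets = [set(np.array(names)[rng.random(6) < 0.7]) for _ in range(10)]
        got = stability_select(sets, 8)
        expect = {m for m in names if sum(m in s for s in sets) >= 8}
        assert got == expect


class TestCrossSampleClassify:
    def test_transfer_with_group_separating_metrics(self, rng):
        n = 120
        labels = np.repeat([0, 1], n // 2)
        deg = rng.standard_normal((n, 4))
        deg[:, 0] += 2.0 * labels
        M = metric_table(deg, rng.standard_normal((n, 4)), list("abcd"))
        out = cross_sample_classify(
            [("deg:a", 1), ("deg:b", -1)], M, labels, k=10, seed=0, n_perm=100
        )
        assert out.estimate > out.ci95[1]
        assert out.significant

    def test_noise_metrics_not_significant(self, rng):
        hits = 0
        for s in range(5):
            n = 100
            labels = np.repeat([0, 1], n // 2)
            M = metric_table(
                rng.standard_normal((n, 3)), rng.standard_normal((n, 3)), list("abc")
            )
            out = cross_sample_classify(
                [("deg:a", 1), ("eff:b", 1)], M, labels, k=10, seed=s, n_perm=100
            )
            hits += out.significant
        assert hits <= 1
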