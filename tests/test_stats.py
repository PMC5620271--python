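"""Cohort statistics: stratification, tests, ROC, DeLong, stepwise,
Spearman/Bonferroni."""

import numpy as np
import pytest
from scipy import stats as sps

from ivimdce import FitError, ValidationError
from ivimdce.stats import (
    compare_auc,
    roc_analysis,
    shapiro_wilk,
    spearman_with_bonferroni,
    stepwise_logistic,
    stratify,
    t_test_from_summary,
    t_test_two_sample,
)


class _Rec:
    def __init__(self, grp):
        self.stage_group = grp


class TestStratify:
    def test_partition_by_stage(self):
        recs = [_Rec("low"), _Rec("high"), _Rec("low"), _Rec("high")]
        low, high = stratify(recs)
        assert len(low) == 2 and len(high) == 2

    def test_empty_input(self):
        low, high = stratify([])
        assert low == [] and high == []

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError, match="stage_group"):
            stratify([_Rec("medium")])


class TestShapiroWilk:
    def test_normal_draws_rarely_rejected(self):
        hits = sum(
            shapiro_wilk(np.random.default_rng(s).normal(size=50))[1] > 0.05
            for s in range(40))
        assert hits >= 36  # >= 90% of seeded repeats

    def test_lognormal_draws_usually_rejected(self):
        hits = sum(
            shapiro_wilk(np.exp(2 * np.random.default_rng(s).normal(size=50)))[1] < 0.05
            for s in range(40))
        assert hits >= 36

    def test_affine_invariance_of_W(self):
        x = np.random.default_rng(1).normal(size=30)
        w1, _ = shapiro_wilk(x)
        w2, _ = shapiro_wilk(5.0 * x - 3.0)
        assert w1 == pytest.approx(w2, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            shapiro_wilk(np.ones(10))


class TestTTest:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = t_test_two_sample(x, x)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_summary_t_on_published_group_row(self):
        """Pooled t from the printed low/high D summary (0.803±0.188,
        n=29 vs 0.700±0.193, n=46) is ≈2.27, p≈0.026 — the value the
        pooled closed form actually implies for that row."""
        t, p = t_test_from_summary(0.803, 0.188, 29, 0.700, 0.193, 46)
        assert t == pytest.approx(2.27, abs=0.01)
        assert p == pytest.approx(0.026, abs=0.002)

    def test_raw_equals_own_summary(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=20), rng.normal(0.5, 1.2, size=30)
        t1, p1 = t_test_two_sample(x, y)
        t2, p2 = t_test_from_summary(x.mean(), x.std(ddof=1), 20,
                                     y.mean(), y.std(ddof=1), 30)
        assert t1 == pytest.approx(t2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            t_test_two_sample(np.ones(5), np.ones(5))


class TestRoc:
    def test_perfect_separation(self):
        v = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.zeros(10), np.ones(10)].astype(bool)
        r = roc_analysis(v, y, direction="higher")
        assert r.auc == pytest.approx(1.0)
        assert r.sens == 1.0 and r.spec == 1.0

    def test_null_marker_auc_near_half(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=500)
        y = rng.random(500) < 0.5
        r = roc_analysis(v, y)
        assert 0.45 <= r.auc <= 0.55

    def test_auc_equals_mann_whitney_identity(self):
        """Trapezoid AUC must equal U/(n1*n2) on arbitrary data with ties."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = rng.integers(20, 60)
            v = np.round(rng.normal(size=n), 1)  # induce ties
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            r = roc_analysis(v, y)
            u = sps.mannwhitneyu(v[y], v[~y], alternative="two-sided").statistic
            assert r.auc == pytest.approx(u / (y.sum() * (~y).sum()), abs=1e-12)

    def test_cutoff_matches_bruteforce_midpoint_search(self):
        """Exhaustive threshold sweep oracle on 20 random datasets."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(15, 50))
            v = rng.normal(size=n)
            y = np.r_[np.zeros(n // 2, bool), np.ones(n - n // 2, bool)]
            v[y] += rng.uniform(0, 2)
            r = roc_analysis(v, y, direction="higher")
            best_j, best_spec, best_cut = -np.inf, -1.0, None
            u = np.unique(v)
            for c in np.r_[u[0] - 1, (u[:-1] + u[1:]) / 2, u[-1] + 1]:
                sens = (v[y] >= c).mean()
                spec = (v[~y] < c).mean()
                j = sens + spec - 1
                if j > best_j or (j == best_j and spec > best_spec):
                    best_j, best_spec, best_cut = j, spec, c
            assert r.sens + r.spec - 1 == pytest.approx(best_j, abs=1e-12)
            assert r.optimal_cutoff == pytest.approx(best_cut)

    def test_lower_direction_flips_rule(self):
        v = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        y = np.array([True, True, True, False, False, False])
        r = roc_analysis(v, y, direction="lower")
        assert r.auc == pytest.approx(1.0)
        assert 3.0 < r.optimal_cutoff < 10.0

    def test_lr_identity_at_cutoff(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=80)
        y = rng.random(80) < 0.5
        v[y] += 1.0
        r = roc_analysis(v, y)
        if r.spec < 1:
            assert r.lr_pos == pytest.approx(r.sens / (1 - r.spec))

    def test_single_class_rejected(self):
        with pytest.raises(FitError, match="both classes"):
            roc_analysis(np.arange(5.0), np.ones(5, bool))


class TestCompareAuc:
    def test_marker_vs_itself_p_one(self):
        rng = np.random.default_rng(10)
        v = rng.normal(size=40)
        y = rng.random(40) < 0.5
        diff, p = compare_auc(v, v, y)
        assert diff == 0.0 and p == 1.0

    def test_strong_vs_noise_marker_detected(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            y = np.r_[np.zeros(100, bool), np.ones(100, bool)]
            strong = rng.normal(size=200) + 2.0 * y
            noise = rng.normal(size=200)
            _, p = compare_auc(strong, noise, y)
            hits += p < 0.01
        assert hits >= 18  # >= 90% power

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        y = rng.random(60) < 0.5
        a = rng.normal(size=60) + y
        b = rng.normal(size=60) + 0.5 * y
        _, p1 = compare_auc(a, b, y)
        _, p2 = compare_auc(np.exp(a), b, y)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestStepwise:
    def test_planted_informative_feature_selected(self):
        sel_info, sel_noise = 0, 0
        runs = 40
        for s in range(runs):
            rng = np.random.default_rng(s)
            X = rng.normal(size=(300, 5))
            logit = 1.2 * X[:, 0]
            y = rng.random(300) < 1 / (1 + np.exp(-logit))
            res = stepwise_logistic(X, y)
            sel_info += "x0" in res.selected
            sel_noise += sum(f"x{j}" in res.selected for j in range(1, 5))
        assert sel_info >= 0.9 * runs
        assert sel_noise <= 0.10 * runs * 4

    def test_null_features_mostly_give_empty_model(self):
        empties = 0
        for s in range(30):
            rng = np.random.default_rng(100 + s)
            X = rng.normal(size=(200, 4))
            y = rng.random(200) < 0.5
            res = stepwise_logistic(X, y)
            empties += len(res.selected) == 0
        assert empties >= 15  # empty model is the most frequent outcome

    def test_duplicated_column_enters_once(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=300)
        y = rng.random(300) < 1 / (1 + np.exp(-2 * x))
        X = np.c_[x, x]
        res = stepwise_logistic(X, y, feature_names=["a", "a_copy"])
        assert len(res.selected) == 1

    def test_perfect_separation_falls_back_penalized(self):
        x = np.r_[np.zeros(20), np.ones(20)] + np.linspace(0, 0.1, 40)
        y = np.r_[np.zeros(20), np.ones(20)]
        X = x[:, None]
        with pytest.warns(RuntimeWarning, match="separation"):
            res = stepwise_logistic(X, y)
        assert res.penalized


class TestSpearmanBonferroni:
    def test_monotone_transform_gives_rho_one(self):
        x = np.linspace(-2, 2, 30)
        res = spearman_with_bonferroni([("x", "expx", x, np.exp(x))])
        assert res[0].rho == pytest.approx(1.0)

    def test_multiplication_rule(self):
        rng = np.random.default_rng(13)
        pairs = []
        for i in range(8):
            x = rng.normal(size=40)
            pairs.append((f"a{i}", f"b{i}", x, x + rng.normal(size=40)))
        res = spearman_with_bonferroni(pairs)
        for r in res:
            assert r.m == 8
            assert r.p_adjusted == pytest.approx(min(1.0, 8 * r.p_raw))
            assert r.p_adjusted >= r.p_raw

    def test_single_pair_adjustment_is_identity(self):
        rng = np.random.default_rng(14)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = spearman_with_bonferroni([("x", "y", x, y)])
        assert res[0].p_adjusted == pytest.approx(res[0].p_raw)

    def test_constant_vector_reported_undefined(self):
        x = np.ones(10)
        y = np.arange(10.0)
        res = spearman_with_bonferroni([("c", "y", x, y)])
        assert np.isnan(res[0].rho) and not res[0].significant
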