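import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tugkit.riskclf import (
    HIGH_RISK,
    LOW_RISK,
    best_trials,
    class_sensitivity_specificity,
    compare_groups,
    feature_subset_search,
    loso_evaluate,
    make_classifiers,
    manova_groups,
    threshold_classify,
)
from tugkit.synth import generate_cohort, three_class_cohort_spec, two_class_cohort_spec

CHEAP = ("nearest_neighbors", "decision_tree", "naive_bayes", "qda")


class TestThreshold:
    def test_boundary_convention(self):
        assert threshold_classify(13.49) == LOW_RISK
        assert threshold_classify(13.5) == HIGH_RISK  # boundary goes to high

    def test_invalid_duration(self):
        with pytest.raises(ValueError, match="invalid duration"):
            threshold_classify(0.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(0.1, 60), st.floats(5, 30), st.floats(0, 10))
    def test_raising_cutoff_never_moves_low_to_high(self, dur, cutoff, bump):
        first = threshold_classify(dur, cutoff)
        second = threshold_classify(dur, cutoff + bump)
        assert not (first == LOW_RISK and second == HIGH_RISK)

    def test_bimodal_cohort_partition_stable_across_cutoffs(self):
        """Durations clustered at ~12 s and ~25 s: any cutoff between
        13 and 16.5 s produces the same split."""
        rng = np.random.default_rng(0)
        durations = np.concatenate(
            [rng.normal(12.0, 0.5, 11), rng.normal(25.0, 2.0, 26)]
        )
        reference = [threshold_classify(d, 13.5) for d in durations]
        for cutoff in np.arange(13.0, 16.51, 0.25):
            assert [threshold_classify(d, cutoff) for d in durations] == reference


class TestCompareGroups:
    def test_identical_groups_null_statistics(self):
        rng = np.random.default_rng(1)
        rows = pd.DataFrame({
            "gait_speed": rng.normal(60, 8, 15),
            "n_steps": rng.normal(10, 2, 15),
        })
        cohort = pd.concat([rows, rows], ignore_index=True)
        groups = np.repeat([0, 1], 15)
        for res in compare_groups(cohort, groups, ("gait_speed", "n_steps")):
            assert res.statistic == pytest.approx(0.0, abs=1e-9)
            assert res.p_value == pytest.approx(1.0)

    def test_small_group_rejected(self):
        cohort = pd.DataFrame({"gait_speed": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="group too small"):
            compare_groups(cohort, np.array([0, 0, 0, 1]), ("gait_speed",))

    def test_rank_branch_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(2)
        # heavy-tailed data forces the rank-sum branch
        x = np.concatenate([rng.standard_cauchy(15), rng.standard_cauchy(15) + 3])
        cohort = pd.DataFrame({"p": x})
        groups = np.repeat([0, 1], 15)
        r1 = compare_groups(cohort, groups, ("p",))[0]
        cohort2 = pd.DataFrame({"p": 5.0 * x + 11.0})
        r2 = compare_groups(cohort2, groups, ("p",))[0]
        assert r1.test_used == r2.test_used == "wilcoxon"
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        cohort = pd.DataFrame({"p": rng.normal(0, 1, 30)})
        groups = rng.integers(0, 2, 30)
        while min((groups == 0).sum(), (groups == 1).sum()) < 3:
            groups = rng.integers(0, 2, 30)
        perm = rng.permutation(30)
        r1 = compare_groups(cohort, groups, ("p",))[0]
        r2 = compare_groups(
            cohort.iloc[perm].reset_index(drop=True), groups[perm], ("p",)
        )[0]
        assert r1.test_used == r2.test_used
        assert r1.p_value == pytest.approx(r2.p_value)


class TestManova:
    def test_single_parameter_reduces_to_anova_f(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        cohort = pd.DataFrame({"p": np.concatenate(
            [rng.normal(0, 1, 20), rng.normal(1, 1, 25)])})
        groups = np.repeat([0, 1], [20, 25])
        F, df1, df2, p = manova_groups(cohort, groups, ("p",))
        f_uni = stats.f_oneway(cohort.p[:20], cohort.p[20:])
        assert F == pytest.approx(f_uni.statistic, rel=1e-6)
        assert p == pytest.approx(f_uni.pvalue, rel=1e-6)
        assert (df1, df2) == (1, 43)

    def test_well_separated_clouds_significant(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, (30, 4))
        b = rng.normal(5, 1, (30, 4))
        cohort = pd.DataFrame(np.vstack([a, b]), columns=list("wxyz"))
        F, df1, df2, p = manova_groups(cohort, np.repeat([0, 1], 30),
                                       ("w", "x", "y", "z"))
        assert p < 1e-3
        assert (df1, df2) == (4, 55)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(60):
            cohort = pd.DataFrame(rng.normal(0, 1, (40, 3)), columns=list("abc"))
            ps.append(manova_groups(cohort, np.repeat([0, 1], 20),
                                    ("a", "b", "c"))[3])
        ps = np.array(ps)
        assert 0.2 < ps.mean() < 0.8
        assert (ps < 0.05).mean() < 0.2


class TestSensitivitySpecificity:
    def test_diagonal_confusion_is_perfect(self):
        conf = np.diag([5, 7, 9])
        for c in range(3):
            assert class_sensitivity_specificity(conf, c) == (1.0, 1.0)

    def test_published_worked_case(self):
        """Two of five class-1 members sent to class 2, all else correct:
        class-1 sensitivity 0.6, specificity 1.0."""
        conf = np.array([[13, 0, 0], [0, 3, 2], [0, 0, 16]])
        assert class_sensitivity_specificity(conf, 1) == (0.6, 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 20), min_size=9, max_size=9))
    def test_matches_bruteforce_counting(self, cells):
        conf = np.array(cells).reshape(3, 3)
        for target in range(3):
            if conf[target].sum() == 0 or conf.sum() < 1:
                continue
            tp = fn = fp = tn = 0
            for i in range(3):
                for j in range(3):
                    n = conf[i, j]
                    if i == target and j == target:
                        tp += n
                    elif i == target:
                        fn += n
                    elif j == target:
                        fp += n
                    else:
                        tn += n
            sens, spec = class_sensitivity_specificity(conf, target)
            assert sens == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert spec == pytest.approx(tn / (tn + fp))

    def test_empty_target_class_flagged(self):
        conf = np.array([[0, 0], [1, 5]])
        with pytest.raises(ValueError, match="sensitivity undefined"):
            class_sensitivity_specificity(conf, 0)


class TestSubsetSearch:
    def separable_cohort(self):
        rng = np.random.default_rng(7)
        n = 30
        df = pd.DataFrame({
            "subject": np.arange(n),
            "trial": 1,
            "total_duration": rng.uniform(10, 30, n),
            "sep": np.concatenate([rng.uniform(0, 1, 15), rng.uniform(3, 4, 15)]),
            "noise": rng.normal(0, 1, n),
        })
        labels = np.repeat([0, 1], 15)
        return df, labels

    def test_perfectly_separable_feature_scores_one(self):
        df, labels = self.separable_cohort()
        res = feature_subset_search(df, labels, features=("sep",),
                                    max_subset=1, classifiers=("decision_tree",),
                                    seed=0)
        assert res.iloc[0].cv_score == 1.0

    def test_cv_score_equals_pooled_confusion_trace(self):
        df, labels = self.separable_cohort()
        X = df[["noise"]].to_numpy()
        model = make_classifiers(0)["naive_bayes"]
        score, conf = loso_evaluate(X, labels, df.subject.to_numpy(), model,
                                    np.unique(labels))
        assert score == pytest.approx(np.trace(conf) / conf.sum())

    def test_permuted_labels_score_near_chance(self):
        rng = np.random.default_rng(9)
        n = 34
        df = pd.DataFrame({
            "subject": np.arange(n), "trial": 1,
            "a": rng.normal(0, 1, n), "b": rng.normal(0, 1, n),
        })
        best = []
        for _ in range(10):
            labels = rng.permutation(np.repeat([0, 1, 2], [12, 11, 11]))
            res = feature_subset_search(df, labels, features=("a", "b"),
                                        max_subset=2,
                                        classifiers=("naive_bayes", "qda"),
                                        seed=0)
            best.append(res.cv_score.max())
        assert np.mean(best) <= 0.55

    def test_fixed_seed_reproducible(self):
        df, labels = self.separable_cohort()
        res1 = feature_subset_search(df, labels, features=("sep", "noise"),
                                     max_subset=2, classifiers=CHEAP, seed=3)
        res2 = feature_subset_search(df, labels, features=("sep", "noise"),
                                     max_subset=2, classifiers=CHEAP, seed=3)
        pd.testing.assert_frame_equal(res1, res2)

    def test_ranking_prefers_smaller_subsets_on_ties(self):
        df, labels = self.separable_cohort()
        res = feature_subset_search(df, labels, features=("sep", "noise"),
                                    max_subset=2,
                                    classifiers=("decision_tree",), seed=0)
        top = res[res.cv_score == res.cv_score.max()]
        assert top.iloc[0].n_features == top.n_features.min()

    def test_duplicate_subject_rows_rejected(self):
        df, labels = self.separable_cohort()
        dup = pd.concat([df, df.iloc[:1]], ignore_index=True)
        with pytest.raises(ValueError, match="one row per subject"):
            feature_subset_search(dup, np.append(labels, 0), features=("sep",),
                                  max_subset=1, classifiers=("naive_bayes",))


def test_best_trials_selects_min_duration():
    cohort = generate_cohort(two_class_cohort_spec(), seed=8)
    best = best_trials(cohort)
    assert len(best) == cohort.subject.nunique()
    assert best.best_trial.all()


def test_three_class_template_supports_good_classification():
    cohort = generate_cohort(three_class_cohort_spec(), seed=4)
    best = best_trials(cohort)
    res = feature_subset_search(
        best, best["grid_class"],
        features=("gait_speed", "speed_to_sit_down", "mean_cadence"),
        max_subset=2, classifiers=("rbf_svm", "naive_bayes"), seed=0,
    )
    assert res.cv_score.max() >= 0.85
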