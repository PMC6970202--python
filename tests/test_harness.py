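import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mmrimmune as mi
from mmrimmune.harness import (
    FeatureMode,
    FeatureSet,
    ModelFamily,
    ModelSpec,
    balanced_subset,
    binary_metrics_from_confusion,
    enumerate_feature_sets,
    evaluate,
    hand_till_auc,
    partition,
    rank_auc,
    run_experiment,
    train_model,
)


def labels_of_sizes(sizes: dict) -> np.ndarray:
    return np.array([c for c, n in sizes.items() for _ in range(n)], dtype=object)


class TestBalancedSubset:
    def test_three_class_study_sizes_give_75(self):
        labels = labels_of_sizes({"LS": 25, "SP": 33, "P": 35})
        assert balanced_subset(labels, seed=0).size == 75

    def test_two_class_pooled_sizes_give_70(self):
        labels = labels_of_sizes({"MMRD": 58, "MMRP": 35})
        assert balanced_subset(labels, seed=0).size == 70

    def test_already_balanced_returns_everything(self):
        labels = labels_of_sizes({"a": 10, "b": 10})
        assert sorted(balanced_subset(labels, seed=3)) == list(range(20))

    def test_deterministic_per_seed_and_no_replacement(self):
        labels = labels_of_sizes({"a": 30, "b": 12})
        s1, s2 = balanced_subset(labels, seed=5), balanced_subset(labels, seed=5)
        assert np.array_equal(s1, s2)
        assert len(set(s1.tolist())) == s1.size
        s3 = balanced_subset(labels, seed=6)
        assert not np.array_equal(s1, s3)

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            balanced_subset(labels_of_sizes({"a": 3}), classes=["a", "b"], seed=0)


class TestPartition:
    def test_two_class_70_into_50_20_is_exactly_stratified(self):
        labels = labels_of_sizes({"MMRD": 35, "MMRP": 35})
        train, test = partition(labels, 50, 20, seed=0)
        assert train.size == 50 and test.size == 20
        for c in ("MMRD", "MMRP"):
            assert (labels[train] == c).sum() == 25
            assert (labels[test] == c).sum() == 10
        assert not set(train) & set(test)

    def test_three_class_75_into_51_24(self):
        labels = labels_of_sizes({"a": 25, "b": 25, "c": 25})
        train, test = partition(labels, 51, 24, seed=0)
        for c in ("a", "b", "c"):
            assert (labels[train] == c).sum() == 17
            assert (labels[test] == c).sum() == 8

    def test_infeasible_stratification_explains(self):
        labels = labels_of_sizes({"a": 25, "b": 25, "c": 25})
        with pytest.raises(ValueError, match="stratify"):
            partition(labels, 50, 25, seed=0)

    def test_seed_changes_membership_not_shape(self):
        labels = labels_of_sizes({"a": 35, "b": 35})
        t1, _ = partition(labels, 50, 20, seed=1)
        t2, _ = partition(labels, 50, 20, seed=2)
        assert sorted(t1) != sorted(t2)
        assert t1.size == t2.size == 50


class TestRankAuc:
    def test_perfect_separation(self):
        assert rank_auc([1, 2, 3, 10, 11], [False, False, False, True, True]) == 1.0

    def test_constant_scores_give_half(self):
        assert rank_auc([5, 5, 5, 5], [True, True, False, False]) == 0.5

    def test_matches_pair_counting(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=20)
        positive = rng.random(20) < 0.4
        if positive.all() or not positive.any():
            positive[0] = not positive[0]
        pairs = [
            1.0 if sp > sn else 0.5 if sp == sn else 0.0
            for sp in scores[positive]
            for sn in scores[~positive]
        ]
        assert rank_auc(scores, positive) == pytest.approx(np.mean(pairs), abs=1e-12)


def brute_force_hand_till(scores, labels, classes):
    """Exhaustive pairwise-comparison oracle for the multiclass AUC."""
    total = 0.0
    for i, j in itertools.combinations(range(len(classes)), 2):
        for pos, col in ((classes[i], i), (classes[j], j)):
            neg = classes[j] if pos == classes[i] else classes[i]
            wins = n = 0
            for a in np.flatnonzero(labels == pos):
                for b in np.flatnonzero(labels == neg):
                    n += 1
                    if scores[a, col] > scores[b, col]:
                        wins += 1
                    elif scores[a, col] == scores[b, col]:
                        wins += 0.5
            total += 0.5 * wins / n
    c = len(classes)
    return 2.0 * total / (c * (c - 1))


class TestHandTill:
    @given(st.integers(0, 500), st.integers(2, 4), st.integers(6, 30))
    def test_equals_exhaustive_pair_oracle(self, seed, n_classes, n):
        rng = np.random.default_rng(seed)
        classes = list("abcd"[:n_classes])
        labels = np.array(classes * (n // n_classes + 1), dtype=object)[:n]
        scores = rng.integers(0, 5, size=(n, n_classes)).astype(float)  # ties likely
        expected = brute_force_hand_till(scores, labels, classes)
        assert hand_till_auc(scores, labels, classes) == pytest.approx(expected, abs=1e-12)

    def test_reduces_to_binary_rank_auc(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(30, 2))
        labels = np.array(["neg"] * 15 + ["pos"] * 15, dtype=object)
        m = hand_till_auc(scores, labels, classes=["neg", "pos"])
        # binary reduction uses the positive-class score column
        assert m == pytest.approx(
            0.5 * (rank_auc(scores[:, 1], labels == "pos") + rank_auc(scores[:, 0], labels == "neg")),
            abs=1e-12,
        )

    def test_perfectly_separated_three_classes(self):
        labels = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5, dtype=object)
        scores = np.zeros((15, 3))
        for k, c in enumerate("abc"):
            scores[labels == c, k] = 10.0
        assert hand_till_auc(scores, labels, classes=list("abc")) == 1.0

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(2)
        n = 3000
        labels = np.array(list("abc") * (n // 3), dtype=object)
        scores = rng.normal(size=(n, 3))
        assert hand_till_auc(scores, labels, classes=list("abc")) == pytest.approx(0.5, abs=0.02)

    def test_class_relabeling_leaves_m_unchanged(self):
        rng = np.random.default_rng(3)
        labels = np.array(list("abc") * 8, dtype=object)
        scores = rng.normal(size=(24, 3))
        m1 = hand_till_auc(scores, labels, classes=list("abc"))
        perm = [2, 0, 1]
        relabeled = np.array([{"a": "b", "b": "c", "c": "a"}[l] for l in labels], dtype=object)
        m2 = hand_till_auc(scores[:, perm], relabeled, classes=list("abc"))
        assert m1 == pytest.approx(m2, abs=1e-12)

    def test_matches_sklearn_one_vs_one_macro(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        labels = np.array(list("abc") * 20, dtype=object)
        raw = rng.random(size=(60, 3)) + 0.5 * (labels[:, None] == np.array(list("abc")))
        proba = raw / raw.sum(axis=1, keepdims=True)
        ours = hand_till_auc(proba, labels, classes=list("abc"))
        theirs = roc_auc_score(labels, proba, multi_class="ovo", average="macro")
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            hand_till_auc(np.zeros((4, 3)), np.array(["a", "a", "b", "b"], dtype=object),
                          classes=list("abc"))


class TestTrainAndEvaluate:
    @pytest.mark.parametrize("family", list(ModelFamily))
    def test_separable_blobs_reach_perfect_accuracy(self, family):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(-5, 0.3, 30), rng.normal(5, 0.3, 30)])[:, None]
        y = np.array(["lo"] * 30 + ["hi"] * 30, dtype=object)
        model = train_model(x, y, ModelSpec(family, cv_folds=3, seed=0))
        report = evaluate(model, x, y, positive_class="hi")
        assert report.accuracy == 1.0 and report.auc == 1.0
        assert report.sensitivity == report.specificity == report.ppv == report.npv == 1.0

    def test_same_seed_gives_identical_scores(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(60, 2))
        y = np.array(["a", "b"] * 30, dtype=object)
        spec = ModelSpec(ModelFamily.FEEDFORWARD_NN, cv_folds=3, seed=9)
        s1 = train_model(x, y, spec).predict_scores(x)
        s2 = train_model(x, y, spec).predict_scores(x)
        assert np.array_equal(s1, s2)

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_model(np.zeros((5, 1)), np.array(["a"] * 5, dtype=object),
                        ModelSpec(ModelFamily.FISHER_DISCRIMINANT))

    def test_printed_confusion_pattern_metrics(self):
        # TP=7 FN=3 TN=10 FP=0: sens 0.70, spec 1.00, PPV 1.00, NPV 10/13
        metrics = binary_metrics_from_confusion(tp=7, fn=3, tn=10, fp=0)
        assert metrics["sensitivity"] == pytest.approx(0.70)
        assert metrics["specificity"] == pytest.approx(1.00)
        assert metrics["ppv"] == pytest.approx(1.00)
        assert metrics["npv"] == pytest.approx(10 / 13)  # ~0.77

    def test_zero_denominator_reported_as_undefined(self):
        metrics = binary_metrics_from_confusion(tp=0, fn=0, tn=5, fp=5)
        assert metrics["sensitivity"] is None
        assert metrics["npv"] is not None


class TestFeatureSets:
    def test_two_class_registry_has_eight_sets_including_cd8ct(self):
        sets = enumerate_feature_sets(FeatureMode.TWO_CLASS)
        assert len(sets) == 8
        names = {s.name for s in sets}
        assert "CD8_CT" in names
        universe = {"CD3_CT", "CD3_IM", "CD8_CT", "CD8_IM"}
        for s in sets:
            assert set(s.columns) <= universe and s.columns

    def test_three_class_family_has_32_sets_of_size_4_to_10(self):
        sets = enumerate_feature_sets(FeatureMode.THREE_CLASS)
        assert len(sets) == 32
        assert len({s.name for s in sets}) == 32
        assert all(4 <= len(s.columns) <= 10 for s in sets)

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError):
            FeatureSet("empty", ())


class TestRunExperiment:
    def test_deterministic_per_seed(self, default_design):
        kwargs = dict(
            feature_set=FeatureSet("CD8_CT", ("CD8_CT",)),
            spec=ModelSpec(ModelFamily.FISHER_DISCRIMINANT),
            mode=FeatureMode.TWO_CLASS,
            n_repeats=3,
            seed=17,
        )
        r1 = run_experiment(default_design, **kwargs)
        r2 = run_experiment(default_design, **kwargs)
        assert r1.summary() == r2.summary()

    def test_margin_features_drop_biopsies(self, default_design):
        result = run_experiment(
            default_design,
            FeatureSet("CD8_IM", ("CD8_IM",)),
            ModelSpec(ModelFamily.FISHER_DISCRIMINANT),
            mode=FeatureMode.TWO_CLASS,
            n_repeats=2,
            seed=0,
        )
        assert result.n_excluded == 27  # the biopsy tumors

    def test_shuffled_labels_sit_at_chance(self, default_design):
        rng = np.random.default_rng(18)
        shuffled = default_design.copy()
        shuffled["cohort"] = rng.permutation(shuffled["cohort"].to_numpy())
        result = run_experiment(
            shuffled,
            FeatureSet("CD8_CT", ("CD8_CT",)),
            ModelSpec(ModelFamily.FISHER_DISCRIMINANT),
            mode=FeatureMode.TWO_CLASS,
            n_repeats=25,
            seed=19,
        )
        summary = result.summary()
        se = summary["sd_accuracy"] / np.sqrt(summary["n_repeats"])
        assert abs(summary["mean_accuracy"] - 0.5) < 4 * max(se, 0.02)

    def test_unknown_feature_column_rejected(self, default_design):
        with pytest.raises(ValueError, match="unknown column"):
            run_experiment(
                default_design,
                FeatureSet("bogus", ("NOT_A_COLUMN",)),
                ModelSpec(ModelFamily.FISHER_DISCRIMINANT),
            )
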