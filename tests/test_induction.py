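"""Threshold-tree induction and the cross-validation harness."""

import numpy as np
import pytest
from sklearn.tree import DecisionTreeClassifier

from conftest import random_spectra

from ecgqc.classifiers import CART_RULES, classify_cart
from ecgqc.covariance import extract_features
from ecgqc.errors import InputError
from ecgqc.induction import (
    FeatureDataset,
    InducedTree,
    Leaf,
    TreeNode,
    cross_validate,
    induce_tree,
    tree_to_rules,
)
from ecgqc.io import QualityLabel

AC, UN = QualityLabel.AC, QualityLabel.UN


def dataset_from_column(col, values, labels, fill=1.0):
    """A dataset where only one log10-eigenvalue column is informative."""
    n = len(values)
    feats = np.full((n, 8), fill)
    # keep rows descending-ish so they resemble real spectra (not required)
    feats[:, col] = values
    ids = [f"r{i}" for i in range(n)]
    return FeatureDataset(record_ids=ids, features=feats, labels=list(labels))


def training_accuracy(tree: InducedTree, data: FeatureDataset) -> float:
    preds = tree.predict(data.features)
    return float(np.mean([p == t for p, t in zip(preds, data.labels)]))


def brute_force_best_depth1_accuracy(x: np.ndarray, labels) -> float:
    """Exhaustive search over all single-feature threshold stumps
    (both leaf-label orientations), plus the constant classifiers."""
    y = np.array([lab == UN for lab in labels])
    n = y.size
    best = max(y.mean(), 1 - y.mean())  # constant classifiers
    for f in range(x.shape[1]):
        values = np.unique(x[:, f])
        thresholds = (values[:-1] + values[1:]) / 2
        for thr in thresholds:
            left = x[:, f] <= thr
            for left_is_un in (True, False):
                pred = np.where(left, left_is_un, not left_is_un)
                best = max(best, float((pred == y).mean()))
    return best


class TestInduceTree:
    def test_separable_data_recovers_threshold(self):
        rng = np.random.default_rng(0)
        un_vals = rng.uniform(-2.0, -0.5, 20)  # log10 lambda_8 small -> UN
        ac_vals = rng.uniform(0.5, 2.0, 20)
        data = dataset_from_column(
            7, np.concatenate([un_vals, ac_vals]), [UN] * 20 + [AC] * 20
        )
        tree = induce_tree(data, max_depth=4, min_leaf=5)
        assert tree.depth() == 1
        assert training_accuracy(tree, data) == 1.0
        root = tree.root
        assert isinstance(root, TreeNode)
        assert root.feature == 7
        assert un_vals.max() < root.threshold < ac_vals.min()

    def test_sklearn_stump_agrees_on_separable_data(self):
        # independent inducer cross-check: same data, same depth budget
        rng = np.random.default_rng(1)
        un_vals = rng.uniform(-2.0, -0.5, 20)
        ac_vals = rng.uniform(0.5, 2.0, 20)
        data = dataset_from_column(
            7, np.concatenate([un_vals, ac_vals]), [UN] * 20 + [AC] * 20
        )
        ours = induce_tree(data, max_depth=4, min_leaf=5)
        ref = DecisionTreeClassifier(max_depth=4, min_samples_leaf=5, random_state=0)
        y = [lab.value for lab in data.labels]
        ref.fit(data.features, y)
        assert ref.score(data.features, y) == training_accuracy(ours, data) == 1.0
        ref_thr = ref.tree_.threshold[0]
        assert un_vals.max() < ref_thr < ac_vals.min()

    def test_single_class_collapses_to_leaf(self):
        data = dataset_from_column(0, np.arange(10.0), [AC] * 10)
        tree = induce_tree(data)
        assert isinstance(tree.root, Leaf)
        assert tree.root.label == AC
        assert tree.root.support == 10
        assert tree.root.errors == 0

    def test_xor_needs_depth_two(self):
        # XOR arrangement on (lambda_1, lambda_8): no depth-1 stump beats
        # chance on the balanced version, but a depth-2 tree is exact on a
        # slightly unbalanced version (greedy needs a nonzero first gain)
        def xor_data(sizes):
            feats, labels = [], []
            for (a, b), m in zip([(0, 0), (0, 1), (1, 0), (1, 1)], sizes):
                for _ in range(m):
                    row = np.full(8, 0.5)
                    row[0] = 5.0 + a
                    row[7] = 1.0 + b
                    feats.append(row)
                    labels.append(UN if a == b else AC)
            ids = [f"r{i}" for i in range(len(feats))]
            return FeatureDataset(
                record_ids=ids, features=np.array(feats), labels=labels
            )

        balanced = xor_data([10, 10, 10, 10])
        assert brute_force_best_depth1_accuracy(
            balanced.features, balanced.labels
        ) == pytest.approx(0.5)

        # unequal corner weights give the center split a nonzero first
        # Gini gain, which a greedy inducer needs to start descending
        skewed = xor_data([14, 10, 10, 10])
        tree = induce_tree(skewed, max_depth=2, min_leaf=1)
        assert tree.depth() == 2
        assert training_accuracy(tree, skewed) == 1.0
        assert brute_force_best_depth1_accuracy(
            skewed.features, skewed.labels
        ) < 1.0

    def test_training_accuracy_non_decreasing_in_depth(self, cohort, cohort_spectra):
        data = FeatureDataset.from_spectra(
            [
                (item.record.record_id, spec, item.label)
                for item, spec in zip(cohort, cohort_spectra)
            ]
        )
        accs = [
            training_accuracy(induce_tree(data, max_depth=d, min_leaf=5), data)
            for d in range(1, 5)
        ]
        assert all(b >= a for a, b in zip(accs, accs[1:]))

    def test_empty_dataset_rejected(self):
        data = FeatureDataset(record_ids=[], features=np.empty((0, 8)), labels=[])
        with pytest.raises(InputError):
            induce_tree(data)

    def test_parameter_recovery_within_class_gap(self):
        rng = np.random.default_rng(2)
        un_vals = rng.uniform(0.0, 1.8, 30)  # lambda_3 rule at log10 = 2.0
        ac_vals = rng.uniform(2.2, 4.0, 30)
        data = dataset_from_column(
            2, np.concatenate([un_vals, ac_vals]), [UN] * 30 + [AC] * 30
        )
        tree = induce_tree(data, max_depth=3, min_leaf=5)
        assert isinstance(tree.root, TreeNode)
        assert un_vals.max() <= tree.root.threshold <= ac_vals.min()


class TestTreeToRules:
    def test_depth1_tree_gives_two_rules(self):
        data = dataset_from_column(
            7, np.concatenate([np.zeros(10) - 1, np.ones(10)]),
            [UN] * 10 + [AC] * 10,
        )
        rules = tree_to_rules(induce_tree(data))
        assert len(rules.rules) == 2

    def test_single_leaf_tree_gives_default_only(self):
        data = dataset_from_column(0, np.arange(10.0), [UN] * 10)
        rules = tree_to_rules(induce_tree(data))
        assert len(rules.rules) == 1
        assert rules.rules[0].conjuncts == ()
        assert rules.rules[0].label == UN

    def test_rules_reproduce_tree_decisions_exactly(self, cohort, cohort_spectra):
        data = FeatureDataset.from_spectra(
            [
                (item.record.record_id, spec, item.label)
                for item, spec in zip(cohort, cohort_spectra)
            ]
        )
        tree = induce_tree(data, max_depth=4, min_leaf=5)
        rules = tree_to_rules(tree)
        for spec in random_spectra(300, seed=13):
            assert rules.classify(spec) == tree.predict_one(spec.log10)

    def test_published_cart_tree_encoded_manually_matches_classifier(self):
        # the two-threshold tree, re-encoded as an induced-tree object and
        # flattened to rules, must agree with the shipped classifier
        tree = InducedTree(
            root=TreeNode(
                feature=7,
                threshold=0.145,
                left=Leaf(label=UN, support=143, errors=6, un_fraction=137 / 143),
                right=TreeNode(
                    feature=0,
                    threshold=5.08,
                    left=Leaf(label=AC, support=788, errors=67, un_fraction=67 / 788),
                    right=Leaf(label=UN, support=67, errors=0, un_fraction=1.0),
                ),
            ),
            n_training=998,
        )
        rules = tree_to_rules(tree, name="cart-manual")
        assert len(rules.rules) == 3
        for spec in random_spectra(1000, seed=17):
            assert rules.classify(spec) == classify_cart(spec)

    def test_shipped_cart_ruleset_matches_classifier_trivially(self):
        for spec in random_spectra(100, seed=19):
            assert CART_RULES.classify(spec) == classify_cart(spec)


class TestCrossValidate:
    @staticmethod
    def toy_dataset(n=40, seed=0):
        rng = np.random.default_rng(seed)
        half = n // 2
        vals = np.concatenate(
            [rng.uniform(-2.0, -0.2, half), rng.uniform(0.2, 2.0, n - half)]
        )
        return dataset_from_column(7, vals, [UN] * half + [AC] * (n - half))

    def test_folds_partition_the_dataset(self):
        data = self.toy_dataset()
        result = cross_validate(data, k=5, seed=1, min_leaf=2)
        assert result.fold_assignment.min() == 0
        assert result.fold_assignment.max() == 4
        counts = np.bincount(result.fold_assignment)
        assert counts.sum() == len(data)
        assert counts.max() - counts.min() <= 1

    def test_stratification_preserves_class_balance(self):
        data = self.toy_dataset(n=40)
        result = cross_validate(data, k=4, seed=2, min_leaf=2)
        y = np.array([lab == UN for lab in data.labels])
        for fold in range(4):
            mask = result.fold_assignment == fold
            assert y[mask].sum() == 5  # 10 UN records over 4 folds stratified

    def test_leave_one_out_on_ten_records(self):
        data = self.toy_dataset(n=10)
        result = cross_validate(data, k=10, seed=3, min_leaf=1)
        counts = np.bincount(result.fold_assignment)
        assert (counts == 1).all() and counts.size == 10

    def test_seeded_determinism(self):
        data = self.toy_dataset()
        a = cross_validate(data, k=5, seed=7, min_leaf=2)
        b = cross_validate(data, k=5, seed=7, min_leaf=2)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
        assert a.pooled == b.pooled
        assert a.auc == b.auc

    def test_k_larger_than_n_rejected(self):
        data = self.toy_dataset(n=6)
        with pytest.raises(InputError):
            cross_validate(data, k=7)
        with pytest.raises(InputError):
            cross_validate(data, k=1)

    def test_separable_data_cross_validates_perfectly(self):
        data = self.toy_dataset(n=60, seed=5)
        result = cross_validate(data, k=6, seed=4, min_leaf=2)
        assert result.pooled.accuracy == 1.0
        assert result.auc == 1.0

    def test_cohort_pipeline_cross_validated_accuracy(self, cohort, cohort_spectra):
        data = FeatureDataset.from_spectra(
            [
                (item.record.record_id, spec, item.label)
                for item, spec in zip(cohort, cohort_spectra)
            ]
        )
        result = cross_validate(data, k=10, seed=7)
        assert result.pooled.accuracy >= 0.9
        assert result.auc >= 0.9


def test_extract_features_roundtrip_into_dataset(cohort, cohort_spectra):
    # FeatureDataset.from_frame inverts the exported feature table
    import pandas as pd

    from ecgqc.covariance import features_frame

    items = [
        (item.record.record_id, spec)
        for item, spec in zip(cohort[:20], cohort_spectra[:20])
    ]
    frame = features_frame(items)
    frame["label"] = [item.label.value for item in cohort[:20]]
    data = FeatureDataset.from_frame(frame)
    assert len(data) == 20
    np.testing.assert_allclose(
        data.features, np.array([s.log10 for _, s in items]), rtol=1e-12
    )
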