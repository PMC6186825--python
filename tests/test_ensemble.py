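"""Splits, base-classifier training, weighting and the weighted vote."""

import numpy as np
import pytest

from conftest import make_ensemble, make_member
from evosvm.connectivity import LabeledFCDataset, PairIndexMap
from evosvm.ensemble import (
    SplitSpec,
    build_ensemble,
    draw_classifier_data,
    predict_batch,
    predict_sample,
    split_inner,
    split_outer,
    train_base_classifier,
)
from evosvm.exceptions import (
    InvalidInputError,
    SplitInfeasibleError,
)


def _dataset(labels, n_feat_regions=6, rng=None, separation=0.0):
    rng = rng or np.random.default_rng(0)
    labels = np.asarray(labels)
    pm = PairIndexMap(n_feat_regions)
    feats = rng.uniform(-0.5, 0.5, size=(labels.size, len(pm)))
    if separation:
        feats[:, 0] = np.clip(0.5 * separation * labels + feats[:, 0] * 0.05, -1, 1)
    return LabeledFCDataset(
        features=feats,
        labels=labels,
        pair_map=pm,
        subject_ids=tuple(f"s{i}" for i in range(labels.size)),
    )


class TestSplits:
    def test_cohort_scale_3_to_1(self, rng):
        # 42 + 38 subjects, 3:1 stratified -> 60 train+validation, 20 test
        labels = np.array([1] * 42 + [-1] * 38)
        ds = _dataset(labels)
        tv, test = split_outer(ds, SplitSpec(), rng)
        assert tv.size == 60 and test.size == 20
        assert set(tv) | set(test) == set(range(80))
        assert set(tv) & set(test) == set()
        for part in (tv, test):
            assert {1, -1} <= set(labels[part])

    def test_smallest_valid_split(self, rng):
        labels = np.array([1, 1, -1, -1])
        ds = _dataset(labels)
        tv, test = split_outer(ds, SplitSpec(), rng)
        assert tv.size >= 1 and test.size >= 1
        assert {1, -1} <= set(labels[tv]) and {1, -1} <= set(labels[test])

    def test_partition_property_over_seeds(self):
        labels = np.array([1] * 13 + [-1] * 9)
        ds = _dataset(labels)
        for seed in range(100):
            tv, test = split_outer(ds, SplitSpec(), np.random.default_rng(seed))
            assert set(tv) | set(test) == set(range(22))
            assert set(tv) & set(test) == set()

    def test_single_subject_class_infeasible(self, rng):
        labels = np.array([1] + [-1] * 7)
        ds = _dataset(labels)
        with pytest.raises(SplitInfeasibleError):
            split_outer(ds, SplitSpec(), rng)

    def test_inner_split_two_to_one(self, rng):
        labels = np.array([1] * 24 + [-1] * 21)
        ds = _dataset(labels)
        tv = np.arange(45)
        train, val = split_inner(tv, ds.labels, SplitSpec(), rng)
        assert train.size == 30 and val.size == 15
        assert set(train) | set(val) == set(tv)
        assert not set(train) & set(val)


class TestDrawClassifierData:
    def test_feature_subset_size_and_membership(self, rng):
        labels = np.array([1, -1] * 30)
        pool = np.arange(4005)
        train, val, subset = draw_classifier_data(
            np.arange(45), labels, pool, 62, SplitSpec(), rng
        )
        assert subset.size == 62 and np.unique(subset).size == 62
        assert np.isin(subset, pool).all()

    def test_full_pool_draw(self, rng):
        labels = np.array([1, -1] * 10)
        pool = np.arange(10)
        _, _, subset = draw_classifier_data(
            np.arange(18), labels, pool, 10, SplitSpec(), rng
        )
        assert sorted(subset) == list(range(10))

    def test_uniform_coverage(self):
        # 200 draws of 3 from 10: P(some feature never drawn) < 1e-6
        labels = np.array([1, -1] * 10)
        seen = set()
        for seed in range(200):
            _, _, subset = draw_classifier_data(
                np.arange(18), labels, np.arange(10), 3, SplitSpec(),
                np.random.default_rng(seed),
            )
            seen.update(subset.tolist())
        assert seen == set(range(10))

    def test_pool_exhausted(self, rng):
        labels = np.array([1, -1] * 10)
        with pytest.raises(SplitInfeasibleError):
            draw_classifier_data(
                np.arange(18), labels, np.arange(5), 6, SplitSpec(), rng
            )


class TestTrainBaseClassifier:
    def test_weight_counts_correct_validation_samples(self, rng):
        # strongly separable feature 0: the SVM predicts the validation part
        # perfectly, so flipping 3 of 9 validation labels gives W = 6/9
        labels = np.array([1, -1] * 12)
        ds = _dataset(labels, rng=rng, separation=1.6)
        flipped = ds.labels.copy()
        val_idx = np.arange(15, 24)
        flip = val_idx[:3]
        flipped[flip] = -flipped[flip]
        ds_flipped = LabeledFCDataset(
            features=ds.features,
            labels=flipped,
            pair_map=ds.pair_map,
            subject_ids=ds.subject_ids,
        )
        member = train_base_classifier(
            ds_flipped, np.arange(15), val_idx, np.arange(5), sigma=3.0, C=1e6
        )
        assert member.weight == pytest.approx(6 / 9, abs=1e-12)

    def test_perfect_validation_gives_weight_one(self, rng):
        labels = np.array([1, -1] * 12)
        ds = _dataset(labels, rng=rng, separation=1.6)
        member = train_base_classifier(
            ds, np.arange(15), np.arange(15, 24), np.arange(5), 3.0, 1e6
        )
        assert member.weight == 1.0

    def test_separable_blobs_hard_margin_training_accuracy(self, rng):
        labels = np.array([1, -1] * 12)
        ds = _dataset(labels, rng=rng, separation=1.6)
        train_idx = np.arange(16)
        member = train_base_classifier(
            ds, train_idx, np.arange(16, 24), np.arange(5), 3.0, 1e6
        )
        pred = member.predict(ds.features[train_idx])
        assert np.mean(pred == ds.labels[train_idx]) == 1.0

    def test_weight_recomputable_from_stored_split(self, rng):
        labels = np.array([1, -1] * 15)
        ds = _dataset(labels, rng=rng)
        member = train_base_classifier(
            ds, np.arange(20), np.arange(20, 30), np.arange(6), 3.0, 1e6
        )
        pred = member.predict(ds.features[member.validation_indices])
        recomputed = np.mean(pred == ds.labels[member.validation_indices])
        assert 0.0 <= member.weight <= 1.0
        assert member.weight == recomputed


class TestBuildEnsemble:
    def test_member_count(self, small_dataset, rng):
        ens = build_ensemble(
            small_dataset, np.arange(16), np.arange(15), 7, 4, 3.0, 1e6,
            SplitSpec(), rng,
        )
        assert len(ens) == 7

    def test_single_member_ensemble(self, small_dataset, rng):
        ens = build_ensemble(
            small_dataset, np.arange(16), np.arange(15), 1, 4, 3.0, 1e6,
            SplitSpec(), rng,
        )
        assert len(ens) == 1
        x = small_dataset.features[0]
        assert predict_sample(ens, x) == int(ens.members[0].predict(x[None])[0])

    def test_determinism_replay(self, small_dataset):
        def build(seed):
            return build_ensemble(
                small_dataset, np.arange(16), np.arange(15), 5, 4, 3.0, 1e6,
                SplitSpec(), np.random.default_rng(seed),
            )

        a, b = build(11), build(11)
        for ma, mb in zip(a.members, b.members):
            np.testing.assert_array_equal(ma.feature_subset, mb.feature_subset)
            np.testing.assert_array_equal(ma.train_indices, mb.train_indices)
            np.testing.assert_array_equal(ma.validation_indices, mb.validation_indices)
            assert ma.weight == mb.weight
        np.testing.assert_array_equal(
            predict_batch(a, small_dataset.features),
            predict_batch(b, small_dataset.features),
        )


class TestWeightedVote:
    def test_weighted_majority_example(self):
        ens = make_ensemble(
            [make_member([0], 0.9, vote=1), make_member([1], 0.9, vote=1),
             make_member([2], 0.7, vote=-1)]
        )
        assert predict_sample(ens, np.zeros(15)) == 1

    def test_tie_goes_to_highest_weight_member(self):
        ens = make_ensemble(
            [make_member([0], 0.8, vote=-1), make_member([1], 0.5, vote=1),
             make_member([2], 0.3, vote=1)]
        )
        # 0.8 each way; the single heaviest member voted -1
        assert predict_sample(ens, np.zeros(15)) == -1

    def test_double_tie_defaults_positive(self):
        ens = make_ensemble(
            [make_member([0], 0.8, vote=-1), make_member([1], 0.8, vote=1)]
        )
        assert predict_sample(ens, np.zeros(15)) == 1

    def test_against_bruteforce_summation(self, rng):
        # 50 random small ensembles with sample-dependent votes
        for trial in range(50):
            n_members = int(rng.integers(1, 8))
            members = [
                make_member([int(rng.integers(0, 15))], float(rng.uniform(0, 1)))
                for _ in range(n_members)
            ]
            ens = make_ensemble(members)
            X = rng.uniform(-1, 1, size=(6, 15))
            got = predict_batch(ens, X)
            for s in range(X.shape[0]):
                votes = [int(m.predict(X[s][None])[0]) for m in members]
                pos = sum(m.weight for m, v in zip(members, votes) if v == 1)
                neg = sum(m.weight for m, v in zip(members, votes) if v == -1)
                if pos != neg:
                    expected = 1 if pos > neg else -1
                else:
                    top = max(m.weight for m in members)
                    top_votes = {v for m, v in zip(members, votes) if m.weight == top}
                    expected = top_votes.pop() if len(top_votes) == 1 else 1
                assert got[s] == expected

    def test_equal_weights_reduce_to_majority(self, rng):
        for trial in range(20):
            n_members = int(rng.integers(1, 9))
            members = [
                make_member([int(rng.integers(0, 15))], 0.6)
                for _ in range(n_members)
            ]
            ens = make_ensemble(members)
            x = rng.uniform(-1, 1, size=15)
            votes = [int(m.predict(x[None])[0]) for m in members]
            majority = 1 if votes.count(1) >= votes.count(-1) else -1
            if votes.count(1) != votes.count(-1):
                assert predict_sample(ens, x) == majority

    def test_member_order_invariance(self, rng):
        members = [
            make_member([int(rng.integers(0, 15))], float(rng.uniform(0.1, 1)))
            for _ in range(6)
        ]
        X = rng.uniform(-1, 1, size=(5, 15))
        a = predict_batch(make_ensemble(members), X)
        b = predict_batch(make_ensemble(members[::-1]), X)
        np.testing.assert_array_equal(a, b)

    def test_batch_equals_per_sample_map(self, rng):
        members = [make_member([i], 0.4 + 0.1 * i) for i in range(4)]
        ens = make_ensemble(members)
        X = rng.uniform(-1, 1, size=(7, 15))
        batch = predict_batch(ens, X)
        singles = [predict_sample(ens, x) for x in X]
        np.testing.assert_array_equal(batch, singles)

    def test_empty_batch(self):
        ens = make_ensemble([make_member([0], 0.9, vote=1)])
        out = predict_batch(ens, np.empty((0, 15)))
        assert out.shape == (0,)

    def test_dimension_mismatch(self):
        ens = make_ensemble([make_member([0], 0.9, vote=1)])
        with pytest.raises(InvalidInputError):
            predict_sample(ens, np.zeros(14))
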