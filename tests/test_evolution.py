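"""Weak-classifier identification, feature-weight accumulation, pruning,
and the evolutionary loop's bookkeeping."""

import numpy as np
import pytest

from conftest import make_ensemble, make_member
from evosvm.config import RunConfig
from evosvm.evolution import (
    EvolutionHistory,
    EvolutionRecord,
    feature_total_weights,
    identify_weak,
    prune_pool,
    run_evolution,
    select_optimal,
)
from evosvm.exceptions import InvalidConfigError, InvalidStateError
from evosvm.simulate import SyntheticSpec, generate_study
from evosvm.connectivity import build_dataset


class TestIdentifyWeak:
    def test_strict_half_boundary(self):
        ens = make_ensemble(
            [make_member([0], 0.2), make_member([1], 0.5), make_member([2], 0.9)]
        )
        weak, strong = identify_weak(ens)
        assert weak.tolist() == [0]
        assert strong.tolist() == [1, 2]

    def test_all_strong(self):
        ens = make_ensemble([make_member([0], 0.5), make_member([1], 0.8)])
        weak, strong = identify_weak(ens)
        assert weak.size == 0 and strong.size == 2

    def test_matches_bruteforce_filter(self, rng):
        for _ in range(20):
            weights = rng.uniform(0, 1, size=rng.integers(1, 12))
            ens = make_ensemble([make_member([i % 15], w) for i, w in enumerate(weights)])
            weak, strong = identify_weak(ens)
            assert weak.tolist() == [i for i, w in enumerate(weights) if w < 0.5]
            assert strong.tolist() == [i for i, w in enumerate(weights) if w >= 0.5]


class TestFeatureTotalWeights:
    def test_accumulates_over_weak_members(self):
        ens = make_ensemble(
            [make_member([3, 4], 0.4), make_member([3], 0.3), make_member([3], 0.9)]
        )
        tw = feature_total_weights(ens, [0, 1])
        assert tw[3] == pytest.approx(0.7)
        assert tw[4] == pytest.approx(0.4)

    def test_strong_only_features_map_to_zero(self):
        ens = make_ensemble([make_member([7], 0.9), make_member([2], 0.2)])
        tw = feature_total_weights(ens, [1])
        assert tw[7] == 0.0

    def test_matches_double_loop_bruteforce(self, rng):
        for _ in range(30):
            n_members = int(rng.integers(1, 30))
            members = [
                make_member(
                    rng.choice(15, size=rng.integers(1, 6), replace=False),
                    float(rng.uniform(0, 1)),
                )
                for _ in range(n_members)
            ]
            ens = make_ensemble(members)
            weak = [l for l, m in enumerate(members) if m.weight < 0.5]
            tw = feature_total_weights(ens, weak)
            for j in range(15):
                expected = 0.0
                for l in weak:
                    if j in members[l].feature_subset:
                        expected += members[l].weight
                assert tw[j] == pytest.approx(expected, abs=1e-12)


class TestPrunePool:
    def test_strict_exceeds_rule(self):
        pool = np.array([10, 11, 12])
        tw = {10: 7.2, 11: 6.9, 12: 7.0}
        new, removed = prune_pool(pool, tw, q=7.0)
        assert removed.tolist() == [10]
        assert new.tolist() == [11, 12]

    def test_noop_when_below_threshold(self):
        pool = np.arange(5)
        new, removed = prune_pool(pool, {j: 1.0 for j in pool}, q=7.0)
        assert removed.size == 0
        np.testing.assert_array_equal(new, pool)

    def test_matches_threshold_scan(self, rng):
        for _ in range(25):
            pool = np.sort(rng.choice(100, size=30, replace=False))
            tw = {int(j): float(rng.uniform(0, 10)) for j in pool}
            q = float(rng.uniform(0, 10))
            new, removed = prune_pool(pool, tw, q)
            expected = sorted(j for j in pool if tw[int(j)] > q)
            assert removed.tolist() == expected
            assert sorted(new.tolist() + removed.tolist()) == pool.tolist()


def _small_study_dataset(seed=0):
    spec = SyntheticSpec(
        n_per_class=(12, 12), region_count=8, n_timepoints=60,
        planted_pairs=((1, 4), (2, 6), (4, 6)), seed=seed,
    )
    study = generate_study(spec)
    return build_dataset(study.series, study.labels)


class TestRunEvolution:
    def test_zero_evolutions_single_generation(self):
        ds = _small_study_dataset()
        cfg = RunConfig(n_members=10, m=5, n_evolutions=0, seed=1)
        hist = run_evolution(ds, cfg)
        assert len(hist.records) == 1
        assert hist.records[0].removed_features.size == 0
        assert hist.records[0].pool_size_after == ds.n_features

    def test_huge_threshold_is_noop_evolution(self):
        ds = _small_study_dataset()
        cfg = RunConfig(n_members=10, m=5, q=1e9, n_evolutions=3, seed=1)
        hist = run_evolution(ds, cfg)
        sizes = {r.pool_size_before for r in hist.records}
        assert sizes == {ds.n_features}

    def test_infeasible_m_rejected_before_work(self):
        ds = _small_study_dataset()
        with pytest.raises(InvalidConfigError):
            run_evolution(ds, RunConfig(n_members=5, m=ds.n_features + 1))

    def test_bookkeeping_replay(self):
        ds = _small_study_dataset(seed=3)
        cfg = RunConfig(n_members=30, m=6, q=0.3, n_evolutions=10, seed=5)
        hist = run_evolution(ds, cfg)
        d = ds.n_features
        cumulative = 0
        all_removed = []
        prev_size = d
        for rec in hist.records:
            assert rec.pool_size_before == d - cumulative
            assert rec.pool_size_after == rec.pool_size_before - rec.removed_features.size
            assert rec.pool_size_before <= prev_size
            prev_size = rec.pool_size_before
            cumulative += rec.removed_features.size
            all_removed.extend(rec.removed_features.tolist())
        assert len(all_removed) == len(set(all_removed))  # pairwise disjoint
        assert not set(all_removed) & set(hist.records[-1].pool_after.tolist())

    def test_end_to_end_determinism(self):
        ds = _small_study_dataset(seed=4)
        cfg = RunConfig(n_members=12, m=5, q=0.5, n_evolutions=4, seed=9)
        h1, h2 = run_evolution(ds, cfg), run_evolution(ds, cfg)
        assert h1.to_frame().equals(h2.to_frame())
        assert h1.optimal_generation == h2.optimal_generation
        np.testing.assert_array_equal(h1.optimal_feature_set, h2.optimal_feature_set)
        for r1, r2 in zip(h1.records, h2.records):
            np.testing.assert_array_equal(r1.removed_features, r2.removed_features)

    def test_no_weak_members_means_no_pruning(self):
        ds = _small_study_dataset()
        cfg = RunConfig(n_members=8, m=5, q=0.0, n_evolutions=2, seed=2)
        hist = run_evolution(ds, cfg)
        for rec in hist.records:
            if rec.weak_count == 0:
                assert rec.removed_features.size == 0


def _history_from_accuracies(accs, tie_break="earliest"):
    cfg = RunConfig(tie_break=tie_break)
    records = []
    pool = 100
    for g, a in enumerate(accs):
        removed = np.array([pool - 1 - g], dtype=int)
        records.append(
            EvolutionRecord(
                generation=g,
                pool_size_before=pool,
                removed_features=removed,
                pool_size_after=pool - 1,
                pool_after=np.setdiff1d(np.arange(pool), removed),
                weak_count=0,
                test_accuracy=float(a),
            )
        )
        pool -= 1
    return EvolutionHistory(
        records=records,
        config=cfg,
        n_features_total=100,
        train_validation_indices=np.arange(10),
        test_indices=np.arange(10, 14),
    )


class TestSelectOptimal:
    def test_earliest_maximum_on_ties(self):
        hist = _history_from_accuracies([0.7, 0.9, 0.9])
        gen, _, _ = select_optimal(hist)
        assert gen == 1  # the earlier of the two 0.9 generations

    def test_single_generation(self):
        hist = _history_from_accuracies([0.8])
        assert select_optimal(hist)[0] == 0

    def test_matches_argmax_oracle(self, rng):
        for _ in range(30):
            accs = rng.uniform(0, 1, size=rng.integers(1, 15)).round(2)
            gen, _, _ = select_optimal(_history_from_accuracies(list(accs)))
            expected = min(
                range(len(accs)), key=lambda g: (-accs[g], g)
            )
            assert gen == expected

    def test_parsimonious_tie_break_prefers_smaller_pool(self):
        hist = _history_from_accuracies([0.9, 0.7, 0.9], tie_break="parsimonious")
        assert select_optimal(hist)[0] == 2  # same accuracy, smaller pool

    def test_empty_history_rejected(self):
        hist = _history_from_accuracies([0.5])
        hist.records = []
        with pytest.raises(InvalidStateError):
            select_optimal(hist)

    def test_feature_set_is_pool_available_to_ensemble(self):
        hist = _history_from_accuracies([0.7, 0.9])
        gen, feats, _ = select_optimal(hist)
        rec = hist.records[gen]
        expected = np.union1d(rec.pool_after, rec.removed_features)
        np.testing.assert_array_equal(feats, expected)
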