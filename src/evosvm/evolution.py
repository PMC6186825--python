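"""The evolutionary feature-elimination loop.

One *evolution* is: build a weighted random SVM ensemble from the active
feature pool, evaluate it on the held-out test split, identify the weak
members (validation accuracy W_l < 0.5, strict), accumulate each feature's
total weight over the weak members that sampled it,

    Tw_j = sum over weak members l of W_l * 1[j in member l's subset],

then remove every feature whose Tw_j strictly exceeds the threshold ``q``
and rebuild from the reduced pool.  Features heavily relied on by weak
classifiers are judged to carry little discriminative information; removed
features never re-enter the pool.

The pool update is subtractive — ``pool := pool \\ {j : Tw_j > q}`` — which
shrinks the pool gradually over generations rather than collapsing it to
the strong members' features in one step.  The generation with the highest
held-out accuracy is the *optimal* evolution and its surviving pool is the
optimal feature set (configurably, the union of features its members
actually drew).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import RunConfig, substream
from .connectivity import LabeledFCDataset
from .ensemble import (
    SplitSpec,
    WeightedEnsemble,
    build_ensemble,
    predict_batch,
    split_outer,
)
from .exceptions import InvalidConfigError, InvalidStateError

__all__ = [
    "FeaturePool",
    "EvolutionRecord",
    "EvolutionHistory",
    "identify_weak",
    "feature_total_weights",
    "prune_pool",
    "run_evolution",
    "select_optimal",
]

logger = logging.getLogger(__name__)


@dataclass
class FeaturePool:
    """The set of feature indices still eligible for sampling."""

    active: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.active = np.unique(np.asarray(self.active, dtype=int))

    def __len__(self) -> int:
        return self.active.size


def identify_weak(ensemble: WeightedEnsemble) -> tuple[np.ndarray, np.ndarray]:
    """Partition member indices into (weak, strong): weak iff W_l < 0.5 strictly."""
    w = ensemble.weights
    weak = np.flatnonzero(w < 0.5)
    strong = np.flatnonzero(w >= 0.5)
    return weak, strong


def feature_total_weights(
    ensemble: WeightedEnsemble, weak_indices: Sequence[int]
) -> dict[int, float]:
    """Total weight Tw_j of every pool feature over the weak members.

    A weak member contributes its full weight W_l to each feature in its
    subset; features sampled by no weak member map to 0.
    """
    tw = {int(j): 0.0 for j in ensemble.feature_pool}
    for l in weak_indices:
        member = ensemble.members[int(l)]
        for j in member.feature_subset:
            tw[int(j)] += member.weight
    return tw


def prune_pool(
    pool: np.ndarray, total_weights: dict[int, float], q: float
) -> tuple[np.ndarray, np.ndarray]:
    """Remove pool features whose total weight strictly exceeds ``q``.

    Returns ``(new_pool, removed)``, both sorted.  A feature with
    ``Tw_j == q`` survives ("exceeds" is strict).
    """
    pool = np.asarray(pool, dtype=int)
    removed = np.array(
        sorted(j for j in pool if total_weights.get(int(j), 0.0) > q), dtype=int
    )
    new_pool = np.setdiff1d(pool, removed)
    return new_pool, removed


def _check_prune_consistency(
    ensemble: WeightedEnsemble,
    weak: np.ndarray,
    removed: np.ndarray,
    q: float,
) -> None:
    """Internal invariant: since every weak weight is < 0.5 (and <= max weak
    weight), Tw_j > q forces feature j to occur in more than q / max_w weak
    members.  Violations indicate a bookkeeping bug."""
    if removed.size == 0 or weak.size == 0:
        return
    weights = ensemble.weights[weak]
    max_w = weights.max()
    counts: dict[int, int] = {}
    for l in weak:
        for j in ensemble.members[int(l)].feature_subset:
            counts[int(j)] = counts.get(int(j), 0) + 1
    for j in removed:
        if not counts.get(int(j), 0) > q / max_w:
            raise InvalidStateError(
                f"pruned feature {j} occurs in {counts.get(int(j), 0)} weak "
                f"members, impossible for Tw > {q} with max weak weight {max_w}"
            )


@dataclass
class EvolutionRecord:
    """Bookkeeping for one generation of the loop."""

    generation: int
    pool_size_before: int
    removed_features: np.ndarray
    pool_size_after: int
    pool_after: np.ndarray
    weak_count: int
    test_accuracy: float
    selection_accuracy: float | None = None
    ensemble_summary: dict = field(default_factory=dict)


@dataclass
class EvolutionHistory:
    """Complete record of a run plus the optimal generation's ensemble."""

    records: list[EvolutionRecord]
    config: RunConfig
    n_features_total: int
    train_validation_indices: np.ndarray
    test_indices: np.ndarray
    selection_indices: np.ndarray | None = None
    optimal_generation: int | None = None
    optimal_feature_set: np.ndarray | None = None
    optimal_ensemble: WeightedEnsemble | None = None
    stop_reason: str = "completed"

    def accuracies(self) -> np.ndarray:
        return np.array([r.test_accuracy for r in self.records])

    def selection_criterion(self) -> np.ndarray:
        """The per-generation accuracy the optimal generation is chosen on."""
        if self.config.selection == "holdout":
            return np.array([r.selection_accuracy for r in self.records])
        return self.accuracies()

    def to_frame(self) -> pd.DataFrame:
        """One row per generation, ready for the history CSV / accuracy plots."""
        return pd.DataFrame(
            {
                "generation": [r.generation for r in self.records],
                "pool_size_before": [r.pool_size_before for r in self.records],
                "removed_count": [len(r.removed_features) for r in self.records],
                "pool_size_after": [r.pool_size_after for r in self.records],
                "weak_count": [r.weak_count for r in self.records],
                "test_accuracy": [r.test_accuracy for r in self.records],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    def to_dict(self) -> dict:
        """Full JSON-serialisable record, removed-feature lists included."""
        return {
            "config": self.config.to_dict(),
            "n_features_total": int(self.n_features_total),
            "train_validation_indices": self.train_validation_indices.tolist(),
            "test_indices": self.test_indices.tolist(),
            "selection_indices": (
                None
                if self.selection_indices is None
                else self.selection_indices.tolist()
            ),
            "optimal_generation": (
                None if self.optimal_generation is None else int(self.optimal_generation)
            ),
            "optimal_feature_set": (
                None
                if self.optimal_feature_set is None
                else [int(j) for j in self.optimal_feature_set]
            ),
            "stop_reason": self.stop_reason,
            "records": [
                {
                    "generation": r.generation,
                    "pool_size_before": r.pool_size_before,
                    "removed_features": [int(j) for j in r.removed_features],
                    "pool_size_after": r.pool_size_after,
                    "weak_count": r.weak_count,
                    "test_accuracy": r.test_accuracy,
                    "selection_accuracy": r.selection_accuracy,
                    "ensemble_summary": r.ensemble_summary,
                }
                for r in self.records
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


def select_optimal(
    history: EvolutionHistory,
) -> tuple[int, np.ndarray, WeightedEnsemble | None]:
    """Generation with maximum held-out accuracy (earliest on ties), its
    feature set, and — when retained in the history — its ensemble."""
    if not history.records:
        raise InvalidStateError("empty evolution history")
    crit = history.selection_criterion()
    best = int(np.argmax(crit))  # argmax returns the earliest maximum
    if history.config.tie_break == "parsimonious":
        # among accuracy-maximal generations, prefer the smallest feature
        # pool (earliest among equal pools); pools are non-increasing
        tied = np.flatnonzero(crit == crit[best])
        pools = np.array([history.records[int(g)].pool_size_before for g in tied])
        best = int(tied[int(np.argmin(pools))])
    record = history.records[best]
    if history.config.optimal_set == "drawn" and history.optimal_ensemble is not None:
        feature_set = history.optimal_ensemble.drawn_features()
    else:
        # the pool this generation's members drew from
        pool_before = np.union1d(record.pool_after, record.removed_features)
        feature_set = pool_before
    ens = history.optimal_ensemble
    if ens is not None and ens.evolution_index != best:
        ens = None
    return best, feature_set, ens


def run_evolution(dataset: LabeledFCDataset, config: RunConfig) -> EvolutionHistory:
    """Run the full loop: build → evaluate → prune → rebuild.

    Stops early (with a logged reason) when fewer than ``m`` features
    remain or pruning empties the pool; always records at least the
    generation-0 ensemble.  Fully reproducible from ``config.seed``.
    """
    d = dataset.n_features
    if config.m > d:
        raise InvalidConfigError(
            f"m={config.m} exceeds the {d} available features (R="
            f"{dataset.region_count})"
        )
    split_spec = SplitSpec(
        outer_ratio=config.outer_ratio,
        inner_ratio=config.inner_ratio,
        stratified=config.stratified,
    )
    tv_idx, test_idx = split_outer(
        dataset, split_spec, substream(config.seed, "outer_split")
    )
    sel_idx: np.ndarray | None = None
    if config.selection == "holdout":
        # carve a selection half out of the test part; the remaining half is
        # the final, never-selected-on test set
        from .ensemble import _split_indices

        test_idx, sel_idx = _split_indices(
            test_idx,
            dataset.labels,
            max(1, test_idx.size // 2),
            config.stratified,
            substream(config.seed, "holdout"),
        )

    pool = FeaturePool(active=np.arange(d), generation=0)
    records: list[EvolutionRecord] = []
    best_acc = -np.inf
    best_pool_size = np.inf
    best_ensemble: WeightedEnsemble | None = None
    stop_reason = "completed"

    for gen in range(config.n_evolutions + 1):
        if len(pool) < config.m:
            stop_reason = (
                f"stopped before generation {gen}: pool size {len(pool)} < m={config.m}"
            )
            logger.info(stop_reason)
            break
        ensemble = build_ensemble(
            dataset,
            tv_idx,
            pool.active,
            config.n_members,
            config.m,
            config.sigma,
            config.C,
            split_spec,
            substream(config.seed, "members", gen),
            evolution_index=gen,
            retry_cap=config.retry_cap,
        )
        pred_test = predict_batch(ensemble, dataset.features[test_idx])
        test_acc = float(np.mean(pred_test == dataset.labels[test_idx]))
        sel_acc: float | None = None
        if sel_idx is not None:
            pred_sel = predict_batch(ensemble, dataset.features[sel_idx])
            sel_acc = float(np.mean(pred_sel == dataset.labels[sel_idx]))

        weak, strong = identify_weak(ensemble)
        if gen < config.n_evolutions:
            tw = feature_total_weights(ensemble, weak)
            new_active, removed = prune_pool(pool.active, tw, config.q)
            _check_prune_consistency(ensemble, weak, removed, config.q)
        else:
            new_active, removed = pool.active, np.empty(0, dtype=int)

        weights = ensemble.weights
        records.append(
            EvolutionRecord(
                generation=gen,
                pool_size_before=len(pool),
                removed_features=removed,
                pool_size_after=int(new_active.size),
                pool_after=new_active,
                weak_count=int(weak.size),
                test_accuracy=test_acc,
                selection_accuracy=sel_acc,
                ensemble_summary={
                    "n_members": len(ensemble),
                    "weak_count": int(weak.size),
                    "strong_count": int(strong.size),
                    "weight_mean": float(weights.mean()),
                    "weight_min": float(weights.min()),
                    "weight_max": float(weights.max()),
                },
            )
        )
        crit = test_acc if sel_acc is None else sel_acc
        take = crit > best_acc or (
            config.tie_break == "parsimonious"
            and crit == best_acc
            and len(pool) < best_pool_size
        )
        if take:
            best_acc = crit
            best_pool_size = len(pool)
            best_ensemble = ensemble
        logger.info(
            "generation %d: pool %d -> %d (removed %d), weak %d/%d, "
            "test accuracy %.4f",
            gen,
            len(pool),
            new_active.size,
            removed.size,
            weak.size,
            len(ensemble),
            test_acc,
        )
        pool = FeaturePool(active=new_active, generation=gen + 1)
        if len(pool) == 0:
            stop_reason = f"stopped after generation {gen}: pruning emptied the pool"
            logger.info(stop_reason)
            break

    history = EvolutionHistory(
        records=records,
        config=config,
        n_features_total=d,
        train_validation_indices=tv_idx,
        test_indices=test_idx,
        selection_indices=sel_idx,
        optimal_ensemble=best_ensemble,
        stop_reason=stop_reason,
    )
    best_gen, feature_set, _ = select_optimal(history)
    history.optimal_generation = best_gen
    history.optimal_feature_set = feature_set
    return history
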