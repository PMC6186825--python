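"""Shared fixtures and ensemble-construction helpers.

``make_member`` builds a genuine :class:`BaseClassifier` whose decision
state is crafted by hand (no training), so voting and weight-accumulation
logic can be tested against brute-force oracles with exactly known votes.
"""

from __future__ import annotations

import numpy as np
import pytest

from evosvm.connectivity import LabeledFCDataset, PairIndexMap
from evosvm.ensemble import BaseClassifier, WeightedEnsemble


def make_member(
    feature_subset,
    weight: float,
    vote: int | None = None,
) -> BaseClassifier:
    """A member with a fixed weight.

    ``vote=+1/-1`` makes the member always predict that label;
    ``vote=None`` makes it predict the sign of its first subset feature
    (so votes vary across samples).  Either way the decision passes
    through the real RBF decision-function code path.
    """
    subset = np.asarray(feature_subset, dtype=int)
    member = BaseClassifier(
        feature_subset=subset,
        train_indices=np.arange(2),
        validation_indices=np.arange(2, 4),
        sigma=3.0,
        C=1e6,
    )
    member.classes = np.array([-1, 1])
    k = subset.size
    if vote is None:
        # two opposed support vectors along the first subset dimension:
        # the kernel difference has the sign of x[subset[0]]
        sv_pos = np.zeros(k)
        sv_pos[0] = 1.0
        member.support_vectors = np.vstack([-sv_pos, sv_pos])
        member.dual_coef = np.array([-1.0, 1.0])
        member.intercept = 0.0
    else:
        member.support_vectors = np.zeros((1, k))
        member.dual_coef = np.array([0.0])
        member.intercept = 1.0 if vote == 1 else -1.0
    member.weight = float(weight)
    return member


def make_ensemble(members, region_count: int = 6, pool=None) -> WeightedEnsemble:
    if pool is None:
        pool = np.arange(region_count * (region_count - 1) // 2)
    return WeightedEnsemble(
        members=list(members), feature_pool=pool, region_count=region_count
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset(rng) -> LabeledFCDataset:
    """20 subjects x 15 FC features (R=6) with a weakly informative feature 0."""
    pm = PairIndexMap(6)
    n = 20
    labels = np.array([1, -1] * (n // 2))
    feats = rng.uniform(-0.5, 0.5, size=(n, len(pm)))
    feats[:, 0] = np.clip(feats[:, 0] + 0.4 * labels, -1, 1)
    return LabeledFCDataset(
        features=feats,
        labels=labels,
        pair_map=pm,
        subject_ids=tuple(f"s{i:02d}" for i in range(n)),
    )
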