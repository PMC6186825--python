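"""Weighted random SVM ensembles.

Each base classifier is an RBF-kernel SVM trained on a random subject
subset (a fresh 2:1 train/validation partition of the "training and
validation" pool) and a random feature subset of size ``m`` drawn without
replacement from the active feature pool.  A member's voting weight ``W_l``
is its accuracy on its own validation part, so ``W_l`` is always in [0, 1]
and is recomputable from the stored split.

Prediction is a weighted vote: per candidate label, the weights of the
members voting for it are summed and the label with the larger total wins.
An exact tie goes to the label voted by the single highest-weight member;
if the top-weight members disagree, the positive class (+1) is returned.
Weak members (``W_l < 0.5``) still vote — the vote is weighted, not
censored.

The RBF bandwidth convention is ``K(u, v) = exp(-||u - v||^2 / (2 sigma^2))``,
i.e. scikit-learn's ``gamma = 1 / (2 sigma^2)``.  A hard-margin SVM is
approximated by a large finite penalty (default ``C = 1e6``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .connectivity import LabeledFCDataset
from .exceptions import (
    DegenerateTrainingError,
    InvalidArgumentError,
    InvalidInputError,
    SplitInfeasibleError,
)

__all__ = [
    "SplitSpec",
    "BaseClassifier",
    "WeightedEnsemble",
    "split_outer",
    "split_inner",
    "draw_classifier_data",
    "train_base_classifier",
    "build_ensemble",
    "predict_sample",
    "predict_batch",
]


@dataclass(frozen=True)
class SplitSpec:
    """Split ratios for the nested partition of subjects.

    ``outer_ratio`` divides all subjects into "training and validation"
    versus test (default 3:1); ``inner_ratio`` divides the former into
    training versus validation (default 2:1).  Stratified splits keep both
    classes in every part, which matters at the small cohort sizes typical
    of clinical fMRI studies.
    """

    outer_ratio: tuple[float, float] = (3.0, 1.0)
    inner_ratio: tuple[float, float] = (2.0, 1.0)
    stratified: bool = True

    def __post_init__(self) -> None:
        for name, ratio in (("outer_ratio", self.outer_ratio),
                            ("inner_ratio", self.inner_ratio)):
            if len(ratio) != 2 or min(ratio) <= 0:
                raise InvalidArgumentError(
                    f"{name} must be two positive numbers, got {ratio!r}"
                )


def _second_part_size(n: int, ratio: tuple[float, float]) -> int:
    """Size of the second part under ``ratio``, nearest-integer rounded,
    with both parts forced non-empty."""
    frac = ratio[1] / (ratio[0] + ratio[1])
    size = int(round(n * frac))
    return min(max(size, 1), n - 1)


def _split_indices(
    indices: np.ndarray,
    labels: np.ndarray,
    second_size: int,
    stratified: bool,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition ``indices`` into (first, second) with |second| = second_size.

    Stratified mode allocates the second part across classes by largest
    remainder, so class proportions are preserved as closely as integers
    allow.  Raises if any part would miss a class.
    """
    indices = np.asarray(indices)
    n = indices.size
    if not (0 < second_size < n):
        raise SplitInfeasibleError(
            f"cannot take {second_size} of {n} subjects and keep both parts non-empty"
        )
    if not stratified:
        perm = rng.permutation(indices)
        return np.sort(perm[second_size:]), np.sort(perm[:second_size])

    part_labels = labels[indices]
    classes = np.unique(part_labels)
    if classes.size < 2:
        raise SplitInfeasibleError("stratified split needs both classes present")
    # largest-remainder apportionment of the second part across classes
    counts = np.array([(part_labels == c).sum() for c in classes])
    if counts.min() < 2:
        raise SplitInfeasibleError(
            "stratified split needs at least 2 subjects per class to keep "
            f"both classes in both parts (class sizes {counts.tolist()})"
        )
    quotas = counts * second_size / n
    take = np.floor(quotas).astype(int)
    remainder_order = np.argsort(-(quotas - take), kind="stable")
    for ci in remainder_order[: second_size - take.sum()]:
        take[ci] += 1
    # each class must appear in both parts; bump the nearest-integer sizes
    # minimally when rounding would empty a class from one part
    take = np.clip(take, 1, counts - 1)
    first_parts, second_parts = [], []
    for c, cnt, t in zip(classes, counts, take):
        cls_idx = rng.permutation(indices[part_labels == c])
        second_parts.append(cls_idx[:t])
        first_parts.append(cls_idx[t:])
    return (
        np.sort(np.concatenate(first_parts)),
        np.sort(np.concatenate(second_parts)),
    )


def split_outer(
    dataset: LabeledFCDataset,
    spec: SplitSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Split all subjects into (train+validation, test) index arrays."""
    indices = np.arange(dataset.n_subjects)
    test_size = _second_part_size(dataset.n_subjects, spec.outer_ratio)
    return _split_indices(indices, dataset.labels, test_size, spec.stratified, rng)


def split_inner(
    train_validation: np.ndarray,
    labels: np.ndarray,
    spec: SplitSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the train+validation pool into (train, validation)."""
    tv = np.asarray(train_validation)
    val_size = _second_part_size(tv.size, spec.inner_ratio)
    return _split_indices(tv, labels, val_size, spec.stratified, rng)


def draw_classifier_data(
    train_validation: np.ndarray,
    labels: np.ndarray,
    feature_pool: np.ndarray,
    m: int,
    spec: SplitSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one member's (train indices, validation indices, feature subset).

    The subject partition is redrawn fresh for every member; features are
    sampled uniformly without replacement from the active pool.
    """
    pool = np.asarray(feature_pool)
    if m > pool.size:
        raise SplitInfeasibleError(
            f"cannot draw m={m} features from a pool of {pool.size}"
        )
    train_idx, val_idx = split_inner(train_validation, labels, spec, rng)
    subset = np.sort(rng.choice(pool, size=m, replace=False))
    return train_idx, val_idx, subset


@dataclass
class BaseClassifier:
    """One trained RBF-SVM with its sampling provenance and voting weight.

    The decision function is stored explicitly (support vectors, dual
    coefficients, intercept) so that a classifier loaded from JSON predicts
    bit-identically to the freshly trained one.
    """

    feature_subset: np.ndarray
    train_indices: np.ndarray
    validation_indices: np.ndarray
    sigma: float
    C: float
    weight: float = field(init=False, default=np.nan)
    support_vectors: np.ndarray = field(init=False, repr=False, default=None)
    dual_coef: np.ndarray = field(init=False, repr=False, default=None)
    intercept: float = field(init=False, default=np.nan)
    classes: np.ndarray = field(init=False, default=None)

    @property
    def gamma(self) -> float:
        return 1.0 / (2.0 * self.sigma**2)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Signed distance-like score on the member's feature subspace.

        ``X`` is indexed in full feature space; the member selects its own
        columns.  Positive score votes ``classes[1]``.
        """
        Xs = np.asarray(X, dtype=float)[:, self.feature_subset]
        sq = cdist(Xs, self.support_vectors, metric="sqeuclidean")
        K = np.exp(-self.gamma * sq)
        return K @ self.dual_coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        score = self.decision_function(X)
        return np.where(score > 0, self.classes[1], self.classes[0])


def train_base_classifier(
    dataset: LabeledFCDataset,
    train_indices: np.ndarray,
    validation_indices: np.ndarray,
    feature_subset: np.ndarray,
    sigma: float,
    C: float,
) -> BaseClassifier:
    """Fit one member and weight it by its validation accuracy."""
    train_indices = np.asarray(train_indices)
    validation_indices = np.asarray(validation_indices)
    if np.intersect1d(train_indices, validation_indices).size:
        raise InvalidArgumentError("train and validation indices overlap")
    y_train = dataset.labels[train_indices]
    if np.unique(y_train).size < 2:
        raise DegenerateTrainingError(
            "training part contains a single class; redraw the member"
        )
    member = BaseClassifier(
        feature_subset=np.asarray(feature_subset, dtype=int),
        train_indices=train_indices,
        validation_indices=validation_indices,
        sigma=float(sigma),
        C=float(C),
    )
    X_train = dataset.features[np.ix_(train_indices, member.feature_subset)]
    svc = SVC(kernel="rbf", C=C, gamma=member.gamma)
    svc.fit(X_train, y_train)
    member.support_vectors = np.asarray(svc.support_vectors_, dtype=float)
    member.dual_coef = np.asarray(svc.dual_coef_[0], dtype=float)
    member.intercept = float(svc.intercept_[0])
    member.classes = np.asarray(svc.classes_, dtype=int)
    y_val = dataset.labels[validation_indices]
    pred = member.predict(dataset.features[validation_indices])
    member.weight = float(np.mean(pred == y_val))
    return member


@dataclass
class WeightedEnsemble:
    """A weighted cluster of base SVMs drawn from one feature pool."""

    members: list[BaseClassifier]
    feature_pool: np.ndarray
    region_count: int
    evolution_index: int = 0

    def __post_init__(self) -> None:
        if not self.members:
            raise InvalidArgumentError("an ensemble needs at least one member")
        self.feature_pool = np.asarray(self.feature_pool, dtype=int)
        pool = set(self.feature_pool.tolist())
        for k, mem in enumerate(self.members):
            if not set(mem.feature_subset.tolist()) <= pool:
                raise InvalidArgumentError(
                    f"member {k} uses features outside the ensemble pool"
                )

    def __len__(self) -> int:
        return len(self.members)

    @property
    def weights(self) -> np.ndarray:
        return np.array([m.weight for m in self.members])

    @property
    def n_features_total(self) -> int:
        from .connectivity import n_features

        return n_features(self.region_count)

    def drawn_features(self) -> np.ndarray:
        """Union of features actually sampled by the members, sorted."""
        return np.unique(np.concatenate([m.feature_subset for m in self.members]))


def build_ensemble(
    dataset: LabeledFCDataset,
    train_validation: np.ndarray,
    feature_pool: np.ndarray,
    n_members: int,
    m: int,
    sigma: float,
    C: float,
    spec: SplitSpec,
    rng: np.random.Generator,
    *,
    evolution_index: int = 0,
    retry_cap: int = 20,
) -> WeightedEnsemble:
    """Build an ensemble of ``n_members`` independently drawn base SVMs.

    A member whose random training part degenerates to one class is
    discarded and redrawn (this cannot happen under stratified inner
    splits); ``retry_cap`` redraws per member before giving up.
    """
    if n_members < 1:
        raise InvalidArgumentError(f"n_members must be >= 1, got {n_members}")
    members: list[BaseClassifier] = []
    for _ in range(n_members):
        for attempt in range(retry_cap + 1):
            train_idx, val_idx, subset = draw_classifier_data(
                train_validation, dataset.labels, feature_pool, m, spec, rng
            )
            try:
                member = train_base_classifier(
                    dataset, train_idx, val_idx, subset, sigma, C
                )
            except DegenerateTrainingError:
                if attempt == retry_cap:
                    raise DegenerateTrainingError(
                        f"single-class training part {retry_cap + 1} times in a "
                        "row; check class balance or enable stratified splits"
                    )
                continue
            members.append(member)
            break
    return WeightedEnsemble(
        members=members,
        feature_pool=np.asarray(feature_pool, dtype=int),
        region_count=dataset.region_count,
        evolution_index=evolution_index,
    )


def _vote_matrix(ensemble: WeightedEnsemble, X: np.ndarray) -> np.ndarray:
    """Per-member predicted labels, shape ``(n_members, n_samples)``."""
    return np.vstack([mem.predict(X) for mem in ensemble.members])


def vote_totals(ensemble: WeightedEnsemble, X: np.ndarray) -> np.ndarray:
    """Summed vote weight per label, shape ``(n_samples, 2)``: columns (-1, +1)."""
    votes = _vote_matrix(ensemble, X)
    w = ensemble.weights[:, None]
    neg = np.sum(w * (votes == -1), axis=0)
    pos = np.sum(w * (votes == 1), axis=0)
    return np.column_stack([neg, pos])


def _resolve_ties(
    ensemble: WeightedEnsemble, votes: np.ndarray, tied: np.ndarray
) -> np.ndarray:
    """Tie rule: label of the single highest-weight member; if the members
    sharing the top weight disagree, +1."""
    w = ensemble.weights
    top = w.max()
    top_votes = votes[w == top, :][:, tied]
    out = np.where(
        (top_votes == top_votes[0]).all(axis=0), top_votes[0], 1
    )
    return out


def predict_batch(ensemble: WeightedEnsemble, X: np.ndarray) -> np.ndarray:
    """Weighted-vote labels for each row of ``X`` (full feature space)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidInputError(f"feature matrix must be 2-D, got shape {X.shape}")
    if X.shape[1] != ensemble.n_features_total:
        raise InvalidInputError(
            f"expected {ensemble.n_features_total} features "
            f"(R={ensemble.region_count}), got {X.shape[1]}"
        )
    if X.shape[0] == 0:
        return np.empty(0, dtype=int)
    votes = _vote_matrix(ensemble, X)
    w = ensemble.weights[:, None]
    neg = np.sum(w * (votes == -1), axis=0)
    pos = np.sum(w * (votes == 1), axis=0)
    out = np.where(pos > neg, 1, -1)
    tied = np.flatnonzero(pos == neg)
    if tied.size:
        out[tied] = _resolve_ties(ensemble, votes, tied)
    return out


def predict_sample(ensemble: WeightedEnsemble, x: Sequence[float]) -> int:
    """Weighted-vote label (+1 or -1) for a single feature vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise InvalidInputError(f"expected a 1-D feature vector, got shape {x.shape}")
    return int(predict_batch(ensemble, x[None, :])[0])
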