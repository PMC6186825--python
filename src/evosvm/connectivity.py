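"""Functional-connectivity feature extraction.

A subject's resting-state recording is summarised as one representative
signal per brain region (a ``T x R`` matrix).  The functional connectivity
(FC) between two regions is the Pearson correlation of their signals, so a
parcellation with ``R`` regions yields ``R*(R-1)/2`` scalar features per
subject — 4005 for the 90-region AAL cerebrum.

Feature indices follow the row-major upper-triangle order
``(0,1), (0,2), ..., (0,R-1), (1,2), ...``; :class:`PairIndexMap` owns the
bijection between indices and unordered region pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import (
    DegenerateSignalError,
    InvalidArgumentError,
    InvalidInputError,
)

__all__ = [
    "ROITimeSeries",
    "PairIndexMap",
    "LabeledFCDataset",
    "n_features",
    "compute_fc_vector",
    "build_dataset",
]


def n_features(region_count: int) -> int:
    """Number of pairwise FC features for ``region_count`` regions.

    >>> n_features(90)
    4005
    """
    if isinstance(region_count, bool) or not isinstance(
        region_count, (int, np.integer)
    ):
        raise InvalidArgumentError(
            f"region_count must be an integer, got {region_count!r}"
        )
    if region_count < 1:
        raise InvalidArgumentError(f"region_count must be >= 1, got {region_count}")
    return region_count * (region_count - 1) // 2


@dataclass(frozen=True)
class ROITimeSeries:
    """One subject's representative region signals, ``T`` timepoints x ``R`` regions."""

    subject_id: str
    signals: np.ndarray

    def __post_init__(self) -> None:
        sig = np.asarray(self.signals, dtype=float)
        if sig.ndim != 2:
            raise InvalidInputError(
                f"subject {self.subject_id!r}: signals must be 2-D (T x R), "
                f"got shape {sig.shape}"
            )
        if sig.shape[0] < 3:
            raise InvalidInputError(
                f"subject {self.subject_id!r}: need at least 3 timepoints, "
                f"got {sig.shape[0]}"
            )
        if sig.shape[1] < 2:
            raise InvalidInputError(
                f"subject {self.subject_id!r}: need at least 2 regions, "
                f"got {sig.shape[1]}"
            )
        if not np.isfinite(sig).all():
            raise InvalidInputError(
                f"subject {self.subject_id!r}: signals contain NaN or infinite values"
            )
        object.__setattr__(self, "signals", sig)

    @property
    def n_timepoints(self) -> int:
        return self.signals.shape[0]

    @property
    def region_count(self) -> int:
        return self.signals.shape[1]


@dataclass(frozen=True)
class PairIndexMap:
    """Bijection between feature index ``k`` and region pair ``(i, j)``, ``i < j``.

    The ordering is row-major over the strict upper triangle and is stable
    across runs, so feature index 0 is always pair (0, 1) and the last index
    is (R-2, R-1).
    """

    region_count: int
    _rows: np.ndarray = field(init=False, repr=False, compare=False)
    _cols: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if isinstance(self.region_count, bool) or not isinstance(
            self.region_count, (int, np.integer)
        ):
            raise InvalidArgumentError(
                f"region_count must be an integer, got {self.region_count!r}"
            )
        if self.region_count < 2:
            raise InvalidArgumentError(
                f"need at least 2 regions for pairs, got {self.region_count}"
            )
        object.__setattr__(self, "region_count", int(self.region_count))
        rows, cols = np.triu_indices(self.region_count, k=1)
        object.__setattr__(self, "_rows", rows)
        object.__setattr__(self, "_cols", cols)

    def __len__(self) -> int:
        return n_features(self.region_count)

    @property
    def n_features(self) -> int:
        return len(self)

    def pair_to_index(self, i: int, j: int) -> int:
        """Feature index of the unordered pair ``(i, j)`` with ``i < j``."""
        R = self.region_count
        if not (0 <= i < j < R):
            raise InvalidArgumentError(
                f"pair ({i}, {j}) invalid: need 0 <= i < j < {R}"
            )
        # closed form of the row-major upper-triangle offset
        return i * (2 * R - i - 1) // 2 + (j - i - 1)

    def index_to_pair(self, k: int) -> tuple[int, int]:
        """Region pair ``(i, j)``, ``i < j``, owning feature index ``k``."""
        if not (0 <= k < len(self)):
            raise InvalidArgumentError(
                f"feature index {k} out of range [0, {len(self)})"
            )
        return int(self._rows[k]), int(self._cols[k])

    def pairs(self) -> np.ndarray:
        """All pairs in index order, shape ``(n_features, 2)``."""
        return np.column_stack([self._rows, self._cols])


def compute_fc_vector(
    ts: ROITimeSeries,
    pair_map: PairIndexMap,
    *,
    on_constant: str = "raise",
) -> np.ndarray:
    """Pearson FC feature vector of one subject, in pair-map index order.

    Parameters
    ----------
    ts
        Region time series, ``T x R``.
    pair_map
        Index map with matching ``region_count``.
    on_constant
        ``"raise"`` (default): a constant region signal is an error naming
        the region.  ``"zero"``: every feature touching a constant region
        is set to 0 and a warning is emitted.
    """
    if ts.region_count != pair_map.region_count:
        raise InvalidInputError(
            f"subject {ts.subject_id!r} has {ts.region_count} regions but the "
            f"pair map expects {pair_map.region_count}"
        )
    if on_constant not in ("raise", "zero"):
        raise InvalidArgumentError(
            f"on_constant must be 'raise' or 'zero', got {on_constant!r}"
        )
    sig = ts.signals
    stds = sig.std(axis=0)
    constant = np.flatnonzero(stds == 0.0)
    if constant.size:
        if on_constant == "raise":
            raise DegenerateSignalError(
                f"subject {ts.subject_id!r}: constant signal in region(s) "
                f"{constant.tolist()}; Pearson correlation is undefined"
            )
        warnings.warn(
            f"subject {ts.subject_id!r}: constant signal in region(s) "
            f"{constant.tolist()}; substituting FC 0 for affected pairs",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sig, rowvar=False)
    if constant.size:
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
    vec = corr[pair_map._rows, pair_map._cols]
    # guard against |r| marginally exceeding 1 through round-off
    return np.clip(vec, -1.0, 1.0)


@dataclass(frozen=True)
class LabeledFCDataset:
    """FC feature matrix with labels: ``N`` subjects x ``d = R(R-1)/2`` features."""

    features: np.ndarray
    labels: np.ndarray
    pair_map: PairIndexMap
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        labs = np.asarray(self.labels, dtype=int)
        if feats.ndim != 2:
            raise InvalidInputError("features must be a 2-D matrix")
        if feats.shape[1] != self.pair_map.n_features:
            raise InvalidInputError(
                f"feature matrix has {feats.shape[1]} columns but the pair map "
                f"defines {self.pair_map.n_features} features"
            )
        if labs.shape != (feats.shape[0],):
            raise InvalidInputError(
                f"labels length {labs.shape} does not match {feats.shape[0]} subjects"
            )
        if len(self.subject_ids) != feats.shape[0]:
            raise InvalidInputError("subject_ids length does not match feature rows")
        bad = set(np.unique(labs)) - {-1, 1}
        if bad:
            raise InvalidInputError(f"labels must be +1/-1, found {sorted(bad)}")
        if feats.shape[0] and len(set(np.unique(labs))) < 2:
            raise InvalidInputError("both classes (+1 and -1) must be present")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labs)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def region_count(self) -> int:
        return self.pair_map.region_count


def build_dataset(
    series: Sequence[ROITimeSeries],
    labels: Mapping[str, int],
    *,
    on_constant: str = "raise",
) -> LabeledFCDataset:
    """Turn per-subject time series plus a subject→label map into a dataset.

    Row order follows the input order of ``series``.  Labels must be +1/-1;
    mapping class names to signs is the caller's (or the IO layer's) job.
    """
    if not series:
        raise InvalidInputError("no subjects given")
    region_counts = {ts.region_count for ts in series}
    if len(region_counts) > 1:
        offenders = {
            ts.subject_id: ts.region_count
            for ts in series
            if ts.region_count != series[0].region_count
        }
        raise InvalidInputError(
            f"inconsistent region counts across subjects: first subject has "
            f"{series[0].region_count}, offenders {offenders}"
        )
    missing = [ts.subject_id for ts in series if ts.subject_id not in labels]
    if missing:
        raise InvalidInputError(f"no label for subject(s): {missing}")
    pair_map = PairIndexMap(series[0].region_count)
    feats = np.vstack(
        [compute_fc_vector(ts, pair_map, on_constant=on_constant) for ts in series]
    )
    labs = np.array([labels[ts.subject_id] for ts in series], dtype=int)
    return LabeledFCDataset(
        features=feats,
        labels=labs,
        pair_map=pair_map,
        subject_ids=tuple(ts.subject_id for ts in series),
    )
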