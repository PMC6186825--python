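"""Discriminative brain-region ranking.

Every FC feature in the optimal set is an unordered region pair; each
selected feature increments the occurrence count of both of its endpoint
regions by one.  Ranking the regions by occurrence frequency (descending,
ties broken by region ordinal) yields the table of most discriminative
regions; the sum of all frequencies is exactly twice the number of
selected features.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .connectivity import PairIndexMap
from .exceptions import EvosvmError, InvalidInputError

__all__ = [
    "RegionTable",
    "RegionFrequencyTable",
    "region_frequencies",
    "top_regions",
    "aal90_names",
]


def aal90_names() -> "RegionTable":
    """The 90 cerebrum region labels of the AAL parcellation, in atlas order
    (left/right alternating, 45 per hemisphere)."""
    text = resources.files("evosvm.data").joinpath("aal90.txt").read_text()
    return RegionTable.from_lines(text.splitlines())


@dataclass(frozen=True)
class RegionTable:
    """Ordered region labels; position in the sequence is the region ordinal."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InvalidInputError(f"duplicate region name(s): {dupes}")
        if not names:
            raise InvalidInputError("region table is empty")
        object.__setattr__(self, "names", names)

    @classmethod
    def from_lines(cls, lines: Iterable[str]) -> "RegionTable":
        return cls(tuple(s.strip() for s in lines if s.strip()))

    def __len__(self) -> int:
        return len(self.names)

    def ordinal(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise InvalidInputError(f"unknown region name {name!r}") from None


@dataclass(frozen=True)
class RegionFrequencyTable:
    """Regions ranked by how many optimal FC features touch them.

    ``ordinals``, ``names`` and ``frequencies`` are parallel sequences in
    rank order (descending frequency, then ascending ordinal); every region
    appears, zeros included.
    """

    ordinals: tuple[int, ...]
    names: tuple[str, ...]
    frequencies: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.ordinals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.names,
                "ordinal": self.ordinals,
                "frequency": self.frequencies,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame()[["region", "frequency"]].to_csv(
            path, index=False, lineterminator="\n"
        )

    def top_k_ordinals(self, k: int) -> tuple[int, ...]:
        return self.ordinals[:k]


def region_frequencies(
    optimal_features: Sequence[int],
    pair_map: PairIndexMap,
    table: RegionTable,
) -> RegionFrequencyTable:
    """Count, per region, the optimal features having it as an endpoint."""
    if len(table) != pair_map.region_count:
        raise InvalidInputError(
            f"region table has {len(table)} names but the pair map expects "
            f"{pair_map.region_count} regions"
        )
    counts = np.zeros(pair_map.region_count, dtype=int)
    for k in optimal_features:
        try:
            i, j = pair_map.index_to_pair(int(k))
        except EvosvmError as exc:
            raise InvalidInputError(str(exc)) from None
        counts[i] += 1
        counts[j] += 1
    order = np.lexsort((np.arange(counts.size), -counts))
    return RegionFrequencyTable(
        ordinals=tuple(int(o) for o in order),
        names=tuple(table.names[o] for o in order),
        frequencies=tuple(int(counts[o]) for o in order),
    )


def top_regions(
    freq_table: RegionFrequencyTable, threshold: int
) -> RegionFrequencyTable:
    """Rows whose frequency strictly exceeds ``threshold``, order preserved."""
    if threshold < 0:
        raise InvalidInputError(f"threshold must be >= 0, got {threshold}")
    keep = [i for i, f in enumerate(freq_table.frequencies) if f > threshold]
    return RegionFrequencyTable(
        ordinals=tuple(freq_table.ordinals[i] for i in keep),
        names=tuple(freq_table.names[i] for i in keep),
        frequencies=tuple(freq_table.frequencies[i] for i in keep),
    )
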