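"""Run configuration.

All tunables in one validated, serialisable record.  Defaults follow the
standard protocol for 90-region FC classification: 500 base classifiers,
62 features per member (≈ sqrt(4005)), RBF bandwidth sigma = 3, an
effectively hard margin (C = 1e6 standing in for an unbounded penalty),
pruning threshold q = 7, 50 evolutions, outer 3:1 and inner 2:1 stratified
splits.

Every output artifact embeds the resolved config verbatim, and all
randomness flows from the single ``seed`` through named substreams — there
is no hidden global RNG state.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Mapping

import numpy as np

from .exceptions import InvalidConfigError

__all__ = ["RunConfig", "substream"]


@dataclass(frozen=True)
class RunConfig:
    n_members: int = 500
    m: int = 62
    sigma: float = 3.0
    C: float = 1e6
    q: float = 7.0
    n_evolutions: int = 50
    outer_ratio: tuple[float, float] = (3.0, 1.0)
    inner_ratio: tuple[float, float] = (2.0, 1.0)
    stratified: bool = True
    seed: int = 0
    positive_label: int = 1
    positive_name: str = "+1"
    negative_name: str = "-1"
    # "pool": optimal feature set = surviving pool of the optimal generation;
    # "drawn": union of features actually sampled by that generation's members
    optimal_set: str = "pool"
    # "test": select the optimal generation on the test split (the protocol
    # the defaults encode; optimistically biased); "holdout": on a separate selection
    # split carved out of the test part
    selection: str = "test"
    # "earliest": ties in the per-generation accuracy go to the earliest
    # generation; "parsimonious": to the accuracy-maximal generation with the
    # smallest feature pool (earliest among those) — the sensible choice when
    # accuracy saturates and generations tie at the ceiling
    tie_break: str = "earliest"
    standardize: bool = False
    retry_cap: int = 20

    def __post_init__(self) -> None:
        errs = []
        if self.n_members < 1:
            errs.append(f"n_members must be >= 1, got {self.n_members}")
        if self.m < 1:
            errs.append(f"m must be >= 1, got {self.m}")
        if self.sigma <= 0:
            errs.append(f"sigma must be positive, got {self.sigma}")
        if self.C <= 0:
            errs.append(f"C must be positive, got {self.C}")
        if self.q < 0:
            errs.append(f"q must be >= 0, got {self.q}")
        if self.n_evolutions < 0:
            errs.append(f"n_evolutions must be >= 0, got {self.n_evolutions}")
        for name in ("outer_ratio", "inner_ratio"):
            r = getattr(self, name)
            if len(r) != 2 or min(r) <= 0:
                errs.append(f"{name} must be two positive numbers, got {r!r}")
        if self.positive_label not in (1, -1):
            errs.append(f"positive_label must be +1 or -1, got {self.positive_label}")
        if self.optimal_set not in ("pool", "drawn"):
            errs.append(f"optimal_set must be 'pool' or 'drawn', got {self.optimal_set!r}")
        if self.selection not in ("test", "holdout"):
            errs.append(f"selection must be 'test' or 'holdout', got {self.selection!r}")
        if self.tie_break not in ("earliest", "parsimonious"):
            errs.append(
                f"tie_break must be 'earliest' or 'parsimonious', got {self.tie_break!r}"
            )
        if not (0 <= int(self.seed) < 2**32):
            errs.append(f"seed must be in [0, 2**32), got {self.seed}")
        if errs:
            raise InvalidConfigError("; ".join(errs))
        object.__setattr__(self, "outer_ratio", tuple(float(v) for v in self.outer_ratio))
        object.__setattr__(self, "inner_ratio", tuple(float(v) for v in self.inner_ratio))

    def replace(self, **changes) -> "RunConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outer_ratio"] = list(self.outer_ratio)
        d["inner_ratio"] = list(self.inner_ratio)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        for name in ("outer_ratio", "inner_ratio"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)


# Named substreams keep the per-purpose RNGs independent of one another and
# of call order; generation-wise streams are indexed by the generation.
_STREAMS = {"outer_split": 1, "members": 2, "simulate": 3, "holdout": 4}


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Derive an independent, reproducible RNG from the master seed."""
    if name not in _STREAMS:
        raise InvalidConfigError(f"unknown RNG substream {name!r}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[name], index))
    return np.random.default_rng(ss)
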