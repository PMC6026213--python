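"""Length-based partitioning of protein datasets.

Training proteins are split into ``k`` disjoint bins by sequence length:
breakpoints ``r_1 < ... < r_{k-1}`` induce the half-open intervals
``(0, r_1], (r_1, r_2], ..., (r_{k-1}, inf)``, which cover every positive
length exactly once.  A query protein is routed to the unique bin whose
interval contains its length, and only that bin's ensemble predicts it.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Sequence, TypeVar

T = TypeVar("T")

#: default breakpoints: six bins (0,100], (100,200], ..., (500, inf)
DEFAULT_BREAKPOINTS = (100.0, 200.0, 300.0, 400.0, 500.0)


@dataclass(frozen=True)
class PartitionScheme:
    """A disjoint cover of (0, inf) by k half-open length intervals."""

    breakpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        bps = tuple(float(b) for b in self.breakpoints)
        if any(b <= 0 for b in bps):
            raise ValueError(f"breakpoints must be positive, got {bps}")
        if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
            raise ValueError(f"breakpoints must be strictly increasing, got {bps}")
        object.__setattr__(self, "breakpoints", bps)

    @property
    def k(self) -> int:
        """Number of bins."""
        return len(self.breakpoints) + 1

    def interval(self, i: int) -> tuple[float, float]:
        """The half-open interval ``(lo, hi]`` of 1-based bin ``i``."""
        if not 1 <= i <= self.k:
            raise ValueError(f"bin index {i} outside 1..{self.k}")
        lo = 0.0 if i == 1 else self.breakpoints[i - 2]
        hi = float("inf") if i == self.k else self.breakpoints[i - 1]
        return lo, hi


def default_scheme() -> PartitionScheme:
    """The six-bin scheme with breakpoints at 100, 200, 300, 400, 500."""
    return PartitionScheme(DEFAULT_BREAKPOINTS)


def assign_bin(L: int, scheme: PartitionScheme) -> int:
    """Return the 1-based bin index i with ``r_{i-1} < L <= r_i``."""
    if L < 1:
        raise ValueError(f"protein length must be >= 1, got {L}")
    # bisect_left counts breakpoints strictly below L, so a length equal
    # to a breakpoint stays in the lower bin (half-open on the left)
    return bisect_left(scheme.breakpoints, L) + 1


def partition_dataset(records: Iterable[T],
                      scheme: PartitionScheme) -> list[list[T]]:
    """Split records into k lists by length; order within bins preserved.

    Records must expose a ``length`` attribute (e.g. ``ProteinRecord``).
    """
    bins: list[list[T]] = [[] for _ in range(scheme.k)]
    for rec in records:
        bins[assign_bin(rec.length, scheme) - 1].append(rec)
    return bins
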