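"""Occurrence-balanced semi-random feature subspaces.

The random subspace method trains each base classifier on a random
subset of the feature space.  The semi-random variant implemented here
adds two constraints tailored to windowed profile features:

* the 20 columns holding the central residue's own profile are part of
  every subspace (they carry the most signal for that residue), and
* the flank features — 120 columns to the left of the central block and
  120 to its right for a 13-residue window — are sampled under an exact
  occurrence-balance condition: across the ``t`` subspaces, every flank
  feature on a side appears exactly ``t*d/120`` times, where ``d`` is
  the number of flank features drawn per side.

Balancing matters because the total pairwise overlap between subspaces,
``sum_{i,j} |S_i ∩ S_j|`` over ordered pairs, equals ``sum_f o_f^2``
where ``o_f`` is the occurrence count of feature ``f``; with the totals
fixed, that sum is minimized exactly when all counts are equal, which
maximizes the diversity of the ensemble's training views.

Subspace dimensions satisfy ``r = 2*d + 20``; the defaults ``t=12``,
``r=160`` give ``d=70`` and an occurrence count of 7 per flank feature.
Balance is reached by a greedy adjustment loop: starting from uniform
random subsets, repeatedly move one occurrence of a currently
most-frequent feature to a currently least-frequent feature inside a
subset that contains the former but not the latter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: size of the profile block that is fixed in every subspace
FIXED_BLOCK_SIZE = 20


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def occurrence_counts(subsets: Sequence[Sequence[int]],
                      pool: Sequence[int]) -> np.ndarray:
    """Count how often each pool feature occurs across the subsets."""
    pos = {f: i for i, f in enumerate(pool)}
    counts = np.zeros(len(pool), dtype=int)
    for sub in subsets:
        for f in sub:
            if f in pos:
                counts[pos[f]] += 1
    return counts


def pairwise_overlap_sum(subsets: Sequence[Sequence[int]]) -> int:
    """Sum of ``|S_i ∩ S_j|`` over all ordered pairs, diagonal included.

    Equals ``sum_f o_f^2`` over the features present in the family.
    """
    sets = [set(s) for s in subsets]
    return sum(len(a & b) for a in sets for b in sets)


def generate_balanced_side(t: int, d: int, pool: Sequence[int],
                           seed) -> list[list[int]]:
    """Generate ``t`` size-``d`` subsets of ``pool`` with exactly equal
    occurrence counts.

    Requires ``t*d`` divisible by ``len(pool)`` and ``d <= len(pool)``;
    every pool feature then occurs exactly ``t*d/len(pool)`` times
    across the subsets.  Deterministic for a fixed seed.  Returned
    subsets are sorted index lists without duplicates.
    """
    pool = list(pool)
    n = len(pool)
    if n == 0:
        raise ValueError("feature pool is empty")
    if d > n:
        raise ValueError(f"subset size d={d} exceeds pool size {n}")
    if (t * d) % n != 0:
        raise ValueError(
            f"t*d = {t}*{d} = {t * d} is not divisible by the pool size {n}; "
            f"exact occurrence balance is impossible"
        )
    rng = _as_rng(seed)
    pool_arr = np.asarray(pool)

    # membership matrix, t x n booleans over pool positions
    member = np.zeros((t, n), dtype=bool)
    for i in range(t):
        member[i, rng.choice(n, size=d, replace=False)] = True

    target = (t * d) // n
    max_moves = 10 * t * d * n
    for _ in range(max_moves):
        counts = member.sum(axis=0)
        mino = counts.min()
        maxo = counts.max()
        if mino == maxo:
            break
        idmin = np.flatnonzero(counts == mino)
        idmax = np.flatnonzero(counts == maxo)
        # candidate subsets: contain some max feature, miss some min feature
        has_max = member[:, idmax].sum(axis=1)
        miss_min = (~member[:, idmin]).sum(axis=1)
        weights = has_max * miss_min
        total = weights.sum()
        if total > 0:
            # uniform draw over triples (i, j, k): pick the subset with
            # probability proportional to its number of valid (j, k) pairs
            i = rng.choice(t, p=weights / total)
            j = rng.choice(idmin[~member[i, idmin]])
            k = rng.choice(idmax[member[i, idmax]])
        else:
            # the strict min/max pairing can be empty while counts are
            # unequal; widen to any donor/receiver pair with a count gap,
            # preferring the largest gap so the imbalance still shrinks
            i, j, k = _widened_move(member, counts, rng)
        member[i, j] = True
        member[i, k] = False
    else:
        raise RuntimeError(
            "subspace balance adjustment did not converge within the move "
            f"budget ({max_moves} moves); t={t}, d={d}, pool={n}"
        )
    return [sorted(pool_arr[np.flatnonzero(member[i])].tolist())
            for i in range(t)]


def _widened_move(member: np.ndarray, counts: np.ndarray,
                  rng: np.random.Generator) -> tuple[int, int, int]:
    """Fallback move: any (subset, receiver j, donor k) with o_j < o_k,
    k in the subset and j not in it, maximizing the count gap."""
    t, n = member.shape
    best: list[tuple[int, int, int]] = []
    best_gap = 0
    for i in range(t):
        inside = np.flatnonzero(member[i])
        outside = np.flatnonzero(~member[i])
        if len(inside) == 0 or len(outside) == 0:
            continue
        k = inside[np.argmax(counts[inside])]
        j = outside[np.argmin(counts[outside])]
        gap = counts[k] - counts[j]
        if gap > best_gap:
            best, best_gap = [(i, j, k)], gap
        elif gap == best_gap and gap > 0:
            best.append((i, j, k))
    if not best:
        raise RuntimeError("no balancing move exists; counts are stuck")
    return best[rng.integers(len(best))]


@dataclass
class SubspaceSet:
    """``t`` feature subspaces of dimension ``r = 2d + 20`` over the
    ``2*pool_size + 20``-dimensional windowed feature space.

    Feature indices are 1-based: the left flank pool is
    ``1..pool_size``, the fixed central block
    ``pool_size+1..pool_size+20``, the right flank pool
    ``pool_size+21..2*pool_size+20``.
    """

    t: int
    d: int
    seed: int
    pool_size: int
    left_subsets: list[list[int]]
    right_subsets: list[list[int]]

    @property
    def r(self) -> int:
        return 2 * self.d + FIXED_BLOCK_SIZE

    @property
    def n_features(self) -> int:
        return 2 * self.pool_size + FIXED_BLOCK_SIZE

    @property
    def fixed_block(self) -> list[int]:
        """1-based indices of the central profile block."""
        return list(range(self.pool_size + 1,
                          self.pool_size + FIXED_BLOCK_SIZE + 1))

    def indices(self, i: int) -> np.ndarray:
        """Sorted 1-based feature indices of subspace ``i`` (0-based i)."""
        return np.asarray(
            sorted(self.left_subsets[i]) + self.fixed_block
            + sorted(self.right_subsets[i]),
            dtype=int,
        )

    def project(self, features: np.ndarray, i: int) -> np.ndarray:
        """Restrict an ``(n, n_features)`` matrix to subspace ``i``."""
        features = np.asarray(features)
        if features.shape[1] != self.n_features:
            raise ValueError(
                f"feature matrix has {features.shape[1]} columns, subspace "
                f"set expects {self.n_features}"
            )
        return features[:, self.indices(i) - 1]

    def full_subsets(self) -> list[list[int]]:
        """The complete subspaces ``S_i = L_i ∪ S_0 ∪ R_i`` as index lists."""
        return [self.indices(i).tolist() for i in range(self.t)]

    def to_json(self) -> str:
        return json.dumps({
            "t": self.t, "d": self.d, "r": self.r, "seed": self.seed,
            "pool_size": self.pool_size,
            "left_subsets": self.left_subsets,
            "right_subsets": self.right_subsets,
        })

    @classmethod
    def from_json(cls, text: str) -> "SubspaceSet":
        obj = json.loads(text)
        return cls(t=obj["t"], d=obj["d"], seed=obj["seed"],
                   pool_size=obj["pool_size"],
                   left_subsets=[list(map(int, s)) for s in obj["left_subsets"]],
                   right_subsets=[list(map(int, s)) for s in obj["right_subsets"]])


def build_subspace_set(t: int = 12, r: int = 160, seed: int = 0,
                       pool_size: int = 120) -> SubspaceSet:
    """Build a balanced subspace set for the default windowed encoding.

    ``r`` must equal ``2*d + 20`` for an integer ``d`` with ``t*d``
    divisible by ``pool_size``.  The left and right flanks are balanced
    independently on separate seed streams.
    """
    if (r - FIXED_BLOCK_SIZE) % 2 != 0 or r <= FIXED_BLOCK_SIZE:
        raise ValueError(
            f"subspace dimension r={r} is not of the form 2*d + "
            f"{FIXED_BLOCK_SIZE} for a positive integer d"
        )
    d = (r - FIXED_BLOCK_SIZE) // 2
    left_pool = list(range(1, pool_size + 1))
    right_pool = list(range(pool_size + FIXED_BLOCK_SIZE + 1,
                            2 * pool_size + FIXED_BLOCK_SIZE + 1))
    left_ss, right_ss = np.random.SeedSequence(seed).spawn(2)
    left = generate_balanced_side(t, d, left_pool, np.random.default_rng(left_ss))
    right = generate_balanced_side(t, d, right_pool, np.random.default_rng(right_ss))
    return SubspaceSet(t=t, d=d, seed=seed, pool_size=pool_size,
                       left_subsets=left, right_subsets=right)
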