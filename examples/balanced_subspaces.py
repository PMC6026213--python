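"""Occurrence-balanced semi-random subspace generation.

Generates the default configuration (t=12 subspaces of dimension r=160
over the 260-dim windowed feature space) and verifies its two defining
properties: every subspace contains the fixed 20-column central block,
and every flank feature occurs exactly t*d/120 = 7 times per side,
which minimizes the total pairwise overlap between subspaces.
"""

from psrsm import build_subspace_set, occurrence_counts, pairwise_overlap_sum

s = build_subspace_set(t=12, r=160, seed=1)
print(f"t={s.t} subspaces, dimension r={s.r} (d={s.d} flank features per side)")

left = occurrence_counts(s.left_subsets, list(range(1, 121)))
right = occurrence_counts(s.right_subsets, list(range(141, 261)))
print(f"left flank occurrences : min={left.min()} max={left.max()} (target 7)")
print(f"right flank occurrences: min={right.min()} max={right.max()} (target 7)")

total = pairwise_overlap_sum(s.full_subsets())
# 12^2 ordered pairs share the 20 fixed columns; each balanced flank
# contributes sum_f o_f^2 = 120 * 7^2
expected = 12 ** 2 * 20 + 2 * 120 * 7 ** 2
print(f"total pairwise overlap sum_ij |S_i ∩ S_j| = {total} "
      f"(theoretical minimum {expected})")
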