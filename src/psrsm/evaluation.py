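"""Q3 accuracy and internal/boundary region accuracy.

Q3 is the percentage of residues whose predicted 3-state class matches
the assigned one: ``Q3 = 100 * (N_H + N_E + N_C) / N`` with ``N_X`` the
correctly predicted residues of class X.  Dataset-level accuracy is the
unweighted mean of per-protein Q3 values over the proteins with valid
predictions (not residue-weighted).

Region accuracy splits residues by local context of the *true*
structure: a residue is internal when both sequence neighbors exist and
share its class, boundary otherwise (chain termini are always
boundary).  By default all three classes enter the tally; the
``he_only`` mode restricts it to helix and strand residues, leaving
coil residues out of both regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

INTERNAL = "internal"
BOUNDARY = "boundary"
EXCLUDED = "excluded"


def q3(pred: str, truth: str) -> float:
    """Percentage of positions where pred and truth agree exactly."""
    if len(pred) != len(truth):
        raise ValueError(
            f"prediction length {len(pred)} != truth length {len(truth)}"
        )
    if len(truth) == 0:
        raise ValueError("empty structure strings")
    matches = sum(p == t for p, t in zip(pred, truth))
    return 100.0 * matches / len(truth)


def average_q3(values: Sequence[float]) -> float:
    """Unweighted arithmetic mean of per-protein Q3 percentages."""
    values = list(values)
    if not values:
        raise ValueError("no Q3 values to average")
    return float(np.mean(values))


def region_mask(truth: str, he_only: bool = False) -> list[str]:
    """Tag each residue of a true-structure string as internal/boundary.

    Internal requires both neighbors to exist and to carry the same
    class; termini are boundary.  With ``he_only``, coil residues are
    tagged ``excluded`` and enter neither region.
    """
    if len(truth) == 0:
        raise ValueError("empty structure string")
    n = len(truth)
    tags = []
    for i, c in enumerate(truth):
        if he_only and c == "C":
            tags.append(EXCLUDED)
        elif 0 < i < n - 1 and truth[i - 1] == c and truth[i + 1] == c:
            tags.append(INTERNAL)
        else:
            tags.append(BOUNDARY)
    return tags


def region_q3(pred: str, truth: str,
              he_only: bool = False) -> tuple[Optional[float], Optional[float]]:
    """Q3 restricted to internal and to boundary residues of the truth.

    Returns ``(internal_q3, boundary_q3)``; a region with no residues
    yields ``None`` and is excluded from any downstream averaging.
    """
    if len(pred) != len(truth):
        raise ValueError(
            f"prediction length {len(pred)} != truth length {len(truth)}"
        )
    tags = region_mask(truth, he_only=he_only)
    out = []
    for region in (INTERNAL, BOUNDARY):
        idx = [i for i, tag in enumerate(tags) if tag == region]
        if not idx:
            out.append(None)
        else:
            out.append(100.0 * sum(pred[i] == truth[i] for i in idx) / len(idx))
    return out[0], out[1]


@dataclass
class EvaluationReport:
    """Per-protein and aggregate Q3 of one prediction set."""

    per_protein: dict[str, float]
    average_q3: float
    internal_q3: Optional[float]
    boundary_q3: Optional[float]
    n: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tq3\n")
            for pid, value in self.per_protein.items():
                fh.write(f"{pid}\t{value:.2f}\n")

    def summary(self) -> dict:
        return {
            "n": self.n,
            "average_q3": round(self.average_q3, 2),
            "internal_q3": (None if self.internal_q3 is None
                            else round(self.internal_q3, 2)),
            "boundary_q3": (None if self.boundary_q3 is None
                            else round(self.boundary_q3, 2)),
        }


def evaluate(predictions: dict[str, str], truths: dict[str, str],
             he_only: bool = False) -> EvaluationReport:
    """Score a set of predictions against true label strings.

    Every predicted id must have a truth entry of equal length.
    Per-protein Q3 values are averaged unweighted; internal and
    boundary accuracies pool residues across all proteins.
    """
    missing = sorted(set(predictions) - set(truths))
    if missing:
        raise ValueError(f"no true labels for predicted id(s): {missing}")
    per_protein: dict[str, float] = {}
    region_correct = {INTERNAL: 0, BOUNDARY: 0}
    region_total = {INTERNAL: 0, BOUNDARY: 0}
    for pid, pred in predictions.items():
        truth = truths[pid]
        if len(pred) != len(truth):
            raise ValueError(
                f"protein {pid!r}: prediction length {len(pred)} != "
                f"truth length {len(truth)}"
            )
        per_protein[pid] = q3(pred, truth)
        for i, tag in enumerate(region_mask(truth, he_only=he_only)):
            if tag == EXCLUDED:
                continue
            region_total[tag] += 1
            region_correct[tag] += pred[i] == truth[i]
    if not per_protein:
        raise ValueError("no proteins to evaluate")

    def pooled(tag: str) -> Optional[float]:
        if region_total[tag] == 0:
            return None
        return 100.0 * region_correct[tag] / region_total[tag]

    return EvaluationReport(
        per_protein=per_protein,
        average_q3=average_q3(list(per_protein.values())),
        internal_q3=pooled(INTERNAL),
        boundary_q3=pooled(BOUNDARY),
        n=len(per_protein),
    )
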