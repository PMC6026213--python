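"""Reading and encoding protein profile data.

This module handles the three plain-text inputs of the pipeline — FASTA
sequences, PSI-BLAST ASCII PSSM profiles and secondary-structure label
strings — plus the two transformations that turn them into classifier
input: the 8-state to 3-state reduction of DSSP assignments and the
sliding-window encoding of per-residue PSSM rows into fixed-length
feature vectors.

Feature matrices are plain ``numpy`` float arrays of shape ``(L, 20*w)``
for a protein of ``L`` residues and an odd window size ``w``.  Residue
and feature indices are 1-based in all documentation and serialized
artifacts; array access is of course 0-based.  For the default ``w=13``
the vector has 260 entries and the profile row of the central residue
always occupies columns 121..140 (1-based).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: the 20 standard amino acids, in the column order PSI-BLAST prints
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: DSSP 8-state to 3-state reduction: helices (H, G, I) to H, strands
#: (E, B) to E, everything else — turns, bends, loops, blanks — to coil.
DSSP8_TO_3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "L": "C", "C": "C", " ": "C",
}


class PSSMParseError(ValueError):
    """Raised when an ASCII PSSM file cannot be parsed."""


@dataclass
class ProteinRecord:
    """One protein: identifier, sequence, PSSM profile, optional labels.

    Parameters
    ----------
    id
        Protein identifier (e.g. a PDB chain id).
    sequence
        Amino-acid string of length ``L >= 1``.  Nonstandard residues
        (X, B, Z, U) are accepted; features come solely from the PSSM.
    pssm
        Real matrix of shape ``(L, 20)`` of per-residue log-odds scores.
    labels3
        Optional 3-state secondary-structure string over ``{H, E, C}``
        of length ``L``.
    """

    id: str
    sequence: str
    pssm: np.ndarray
    labels3: Optional[str] = None

    def __post_init__(self) -> None:
        self.pssm = np.asarray(self.pssm, dtype=float)
        L = len(self.sequence)
        if L < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        if self.pssm.ndim != 2 or self.pssm.shape != (L, 20):
            raise ValueError(
                f"protein {self.id!r}: PSSM shape {self.pssm.shape} does not "
                f"match sequence length {L} (expected ({L}, 20))"
            )
        if self.labels3 is not None:
            if len(self.labels3) != L:
                raise ValueError(
                    f"protein {self.id!r}: label string length "
                    f"{len(self.labels3)} != sequence length {L}"
                )
            bad = set(self.labels3) - set("HEC")
            if bad:
                raise ValueError(
                    f"protein {self.id!r}: labels contain non-HEC "
                    f"characters {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


def parse_pssm(path) -> np.ndarray:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into an ``(L, 20)`` matrix.

    Only the first score block (the 20 log-odds columns) is returned;
    the weighted-percentage block and the trailing per-row statistics,
    when present, are ignored.

    Raises
    ------
    PSSMParseError
        If the file contains no residue rows, or a residue row does not
        carry at least 20 numeric scores.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if len(tokens) < 2:
                continue
            # a residue row starts with a position number and a single
            # residue letter; anything else is header or footer
            if not tokens[0].lstrip("-").isdigit():
                continue
            if len(tokens[1]) != 1 or not tokens[1].isalpha():
                continue
            scores = []
            for tok in tokens[2:22]:
                try:
                    scores.append(float(tok))
                except ValueError:
                    break
            if len(scores) != 20:
                raise PSSMParseError(
                    f"{path}:{lineno}: residue row has {len(scores)} scores, "
                    f"expected 20: {line.rstrip()!r}"
                )
            rows.append(scores)
    if not rows:
        raise PSSMParseError(f"{path}: no residue score rows found")
    return np.array(rows, dtype=float)


def write_pssm(path, sequence: str, pssm: np.ndarray) -> None:
    """Write an ``(L, 20)`` matrix in the PSI-BLAST ASCII PSSM layout.

    The layout mirrors ``-out_ascii_pssm``: two header lines, a column
    header, then one row per residue with position, residue letter, the
    20 scores, a second 20-column block (written as zeros, standing in
    for the weighted-percentage block) and two trailing statistics.
    Integer-valued scores are written as integers so hand-written
    integer fixtures round-trip exactly.
    """
    pssm = np.asarray(pssm, dtype=float)
    if pssm.shape != (len(sequence), 20):
        raise ValueError(
            f"PSSM shape {pssm.shape} does not match sequence length "
            f"{len(sequence)}"
        )

    def fmt(x: float) -> str:
        return f"{int(x):d}" if float(x).is_integer() else f"{x:.4f}"

    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted "
            "observed percentages rounded down, information per position, "
            "and relative weight of gapless real matches to pseudocounts\n"
        )
        fh.write("            " + "  ".join(AMINO_ACIDS) + "   "
                 + "  ".join(AMINO_ACIDS) + "\n")
        for i, aa in enumerate(sequence):
            scores = " ".join(f"{fmt(v):>7s}" for v in pssm[i])
            pct = " ".join(f"{0:>3d}" for _ in range(20))
            fh.write(f"{i + 1:5d} {aa} {scores}  {pct}  0.00 0.00\n")


def reduce_dssp8_to3(labels8: str) -> str:
    """Reduce an 8-state DSSP string to the 3-state H/E/C alphabet.

    H, G and I become helix (H); E and B become strand (E); T, S, L,
    C and blank become coil (C).
    """
    out = []
    for pos, ch in enumerate(labels8, start=1):
        try:
            out.append(DSSP8_TO_3[ch])
        except KeyError:
            raise ValueError(
                f"unknown secondary-structure state {ch!r} at position {pos}"
            ) from None
    return "".join(out)


def scale_pssm(pssm: np.ndarray, scaling: str) -> np.ndarray:
    """Apply elementwise scaling to raw log-odds scores.

    ``"sigmoid"`` maps each score x to 1/(1+e^-x), bounding inputs to
    (0, 1); ``"none"`` passes raw scores through.
    """
    if scaling == "none":
        return np.asarray(pssm, dtype=float)
    if scaling == "sigmoid":
        x = np.asarray(pssm, dtype=float)
        return 1.0 / (1.0 + np.exp(-x))
    raise ValueError(f"unknown scaling mode {scaling!r}; use 'none' or 'sigmoid'")


def encode_windows(pssm: np.ndarray, w: int = 13,
                   scaling: str = "sigmoid") -> np.ndarray:
    """Encode each residue as the concatenated PSSM rows of a w-window.

    Scaling is applied first; ``w//2`` all-zero rows are then inserted
    before and after the chain, so windows that extend past a terminus
    carry literal zero blocks.  Row ``i`` (0-based) of the result is the
    concatenation of the padded rows ``i .. i+w-1``, i.e. the profile
    context of residues ``i-w//2 .. i+w//2``.  For ``w=13`` the output
    has 260 columns and columns 121..140 (1-based) hold the scaled
    profile of the central residue itself.
    """
    if w % 2 == 0 or w < 1:
        raise ValueError(f"window size must be odd and positive, got {w}")
    pssm = np.asarray(pssm, dtype=float)
    if pssm.ndim != 2 or pssm.shape[0] < 1 or pssm.shape[1] != 20:
        raise ValueError(f"PSSM must be a non-empty (L, 20) matrix, got shape "
                         f"{pssm.shape}")
    L = pssm.shape[0]
    half = w // 2
    scaled = scale_pssm(pssm, scaling)
    padded = np.vstack([np.zeros((half, 20)), scaled, np.zeros((half, 20))])
    idx = np.arange(L)[:, None] + np.arange(w)[None, :]
    return padded[idx].reshape(L, w * 20)


def central_block(w: int = 13) -> tuple[int, int]:
    """1-based inclusive column range of the central residue's profile."""
    half = w // 2
    return (20 * half + 1, 20 * half + 20)


# ---------------------------------------------------------------------------
# file round-trip helpers for the FASTA + PSSM + labels trio
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=pid, description="")
               for pid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_labels(path) -> dict[str, str]:
    """Read a labels file: one line ``id<TAB>HEC-string`` per protein."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'id<TAB>labels', got "
                    f"{line!r}"
                )
            out[parts[0]] = parts[1]
    return out


def write_labels(path, labels: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for pid, lab in labels.items():
            fh.write(f"{pid}\t{lab}\n")
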