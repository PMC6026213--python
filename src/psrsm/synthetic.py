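"""Synthetic labeled proteins with PSSM-like profiles.

The generator emulates the statistical structure the prediction method
relies on, without any database search:

* secondary-structure labels follow a 3-state semi-Markov chain with
  geometric run lengths, so helices/strands/coils form realistic
  contiguous segments and the internal/boundary evaluation is
  exercised;
* each residue's 20-dim profile row is drawn from a class-conditional
  Gaussian (class mean + isotropic noise), then convexly smoothed with
  its sequence neighbors so nearby residues are correlated the way
  windowed profiles are;
* an optional length effect shifts the class means by a bin-specific
  direction, planting the signal that makes length-routed ensembles
  outperform mismatched ones.

Profiles are continuous rather than integer log-odds; the window
encoder is agnostic to integrality.  All randomness flows from one
master seed through fixed substreams, so identical configs reproduce
byte-identical datasets.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (AMINO_ACIDS, ProteinRecord, write_fasta, write_labels,
                 write_pssm)
from .partition import PartitionScheme

CLASSES = ("H", "E", "C")


def separated_class_means(separation: float = 3.0) -> np.ndarray:
    """Three 20-dim class means with equal pairwise Euclidean distance.

    Each class elevates a disjoint block of profile columns; the block
    height is chosen so every pair of means is ``separation`` apart.
    With unit noise sd, ``separation=3`` is a strongly separable
    problem and ``separation=0`` is pure noise.
    """
    blocks = [slice(0, 7), slice(7, 14), slice(14, 20)]
    means = np.zeros((3, 20))
    if separation > 0:
        for row, blk in zip(means, blocks):
            row[blk] = 1.0
        # block widths are 7/7/6, so raw pairwise distances differ by a
        # few percent; rescale so the smallest is exactly `separation`
        d = min(np.linalg.norm(means[i] - means[j])
                for i in range(3) for j in range(i + 1, 3))
        means *= separation / d
    return means


@dataclass
class SyntheticConfig:
    """Conditions of a synthetic dataset.

    ``length_ranges`` are inclusive ``(lo, hi)`` intervals, one per
    length bin, sampled with ``length_weights``; ``class_means`` is a
    3x20 array in H, E, C order; ``noise_sd`` the within-class profile
    sd; ``neighbor_smoothing`` the convex weight given to the neighbor
    average; ``run_length_means`` the mean segment length per class
    (geometric runs, so class frequencies are proportional to these
    means); ``length_effect`` the magnitude of the per-bin class-mean
    shift in profile units.
    """

    n_proteins: int = 200
    length_ranges: tuple[tuple[int, int], ...] = ((30, 100), (101, 200),
                                                  (201, 300))
    length_weights: tuple[float, ...] = (1.0, 1.0, 1.0)
    class_means: np.ndarray = field(default_factory=separated_class_means)
    noise_sd: float = 1.0
    neighbor_smoothing: float = 0.3
    run_length_means: dict = field(
        default_factory=lambda: {"H": 6.0, "E": 4.5, "C": 8.0})
    length_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_means = np.asarray(self.class_means, dtype=float)
        if self.class_means.shape != (3, 20):
            raise ValueError("class_means must be a 3x20 array (H, E, C rows)")
        if len(self.length_ranges) != len(self.length_weights):
            raise ValueError("one length weight per length range required")
        for lo, hi in self.length_ranges:
            if not (1 <= lo <= hi):
                raise ValueError(f"invalid length range ({lo}, {hi})")
        if not all(w >= 0 for w in self.length_weights) \
                or sum(self.length_weights) <= 0:
            raise ValueError("length weights must be non-negative, sum > 0")
        if not 0 <= self.neighbor_smoothing < 1:
            raise ValueError("neighbor smoothing must lie in [0, 1)")
        if any(m < 1 for m in self.run_length_means.values()):
            raise ValueError("mean run lengths must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")
        if self.length_effect < 0:
            raise ValueError("length effect must be >= 0")

    def scheme(self) -> PartitionScheme:
        """Partition scheme whose bins match the config's length ranges."""
        return PartitionScheme(tuple(float(hi) for _, hi
                                     in self.length_ranges[:-1]))


def _bin_shifts(cfg: SyntheticConfig) -> np.ndarray:
    """Per-(bin, class) unit shift directions, fixed by the config seed.

    Drawn on a dedicated substream so train and test splits generated
    from the same config see identical shifts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 777]))
    shifts = rng.normal(size=(len(cfg.length_ranges), 3, 20))
    shifts /= np.linalg.norm(shifts, axis=2, keepdims=True)
    return shifts


def _sample_labels(L: int, cfg: SyntheticConfig,
                   rng: np.random.Generator) -> str:
    """Semi-Markov H/E/C chain: geometric runs, uniform switch among the
    other two classes, stationary start (class frequency ∝ mean run)."""
    means = np.array([cfg.run_length_means[c] for c in CLASSES])
    stationary = means / means.sum()
    labels = []
    state = int(rng.choice(3, p=stationary))
    while len(labels) < L:
        run = int(rng.geometric(1.0 / means[state]))
        labels.extend(CLASSES[state] * run)
        state = int(rng.choice([s for s in range(3) if s != state]))
    return "".join(labels[:L])


def _smooth(X: np.ndarray, a: float) -> np.ndarray:
    """Convex combination of each row with the mean of its neighbors."""
    if a == 0 or X.shape[0] < 2:
        return X
    nb = np.empty_like(X)
    nb[0] = X[1]
    nb[-1] = X[-2]
    if X.shape[0] > 2:
        nb[1:-1] = 0.5 * (X[:-2] + X[2:])
    return (1 - a) * X + a * nb


def generate_dataset(cfg: SyntheticConfig) -> list[ProteinRecord]:
    """Generate ``cfg.n_proteins`` labeled records under the config."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    return _generate(cfg, cfg.n_proteins, rng, prefix="syn")


def _generate(cfg: SyntheticConfig, n: int, rng: np.random.Generator,
              prefix: str) -> list[ProteinRecord]:
    weights = np.asarray(cfg.length_weights, dtype=float)
    weights = weights / weights.sum()
    shifts = _bin_shifts(cfg)
    class_idx = {c: i for i, c in enumerate(CLASSES)}
    records = []
    for p in range(n):
        b = int(rng.choice(len(cfg.length_ranges), p=weights))
        lo, hi = cfg.length_ranges[b]
        L = int(rng.integers(lo, hi + 1))
        labels = _sample_labels(L, cfg, rng)
        means = cfg.class_means + cfg.length_effect * shifts[b]
        rows = means[[class_idx[c] for c in labels]]
        X = rows + rng.normal(scale=cfg.noise_sd, size=(L, 20))
        X = _smooth(X, cfg.neighbor_smoothing)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        records.append(ProteinRecord(id=f"{prefix}{p:04d}", sequence=seq,
                                     pssm=X, labels3=labels))
    return records


def generate_length_routed_benchmark(
        cfg: SyntheticConfig,
        test_fraction: float = 0.25,
) -> tuple[list[ProteinRecord], list[list[ProteinRecord]]]:
    """Train records plus per-bin test records with a planted length effect.

    Proteins are generated under the config (which should set a nonzero
    ``length_effect``), then split per bin into disjoint train/test
    subsets.  Returns ``(train, tests)`` with ``tests[i]`` the held-out
    proteins of bin ``i``; raises if any bin ends up without both train
    and test proteins.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test fraction must lie in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    records = _generate(cfg, cfg.n_proteins, rng, prefix="bench")
    scheme = cfg.scheme()
    from .partition import partition_dataset  # local to avoid cycle at import
    bins = partition_dataset(records, scheme)
    train: list[ProteinRecord] = []
    tests: list[list[ProteinRecord]] = []
    for i, bin_records in enumerate(bins, start=1):
        n_test = int(round(test_fraction * len(bin_records)))
        if len(bin_records) - n_test < 1 or n_test < 1:
            raise ValueError(
                f"bin {i} has {len(bin_records)} proteins; not enough for a "
                f"train/test split (increase n_proteins or its weight)"
            )
        order = rng.permutation(len(bin_records))
        tests.append([bin_records[j] for j in order[:n_test]])
        train.extend(bin_records[j] for j in order[n_test:])
    return train, tests


def write_dataset(records, outdir) -> Path:
    """Write the FASTA + ASCII-PSSM + labels trio plus a train manifest.

    Emits ``proteins.fasta``, ``pssm/<id>.pssm``, ``labels.tsv`` and
    ``manifest.tsv`` (``id<TAB>fasta<TAB>pssm<TAB>labels``), the exact
    formats the training and prediction commands consume.
    """
    outdir = Path(outdir)
    (outdir / "pssm").mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "proteins.fasta",
                {rec.id: rec.sequence for rec in records})
    labels = {}
    with open(outdir / "manifest.tsv", "w") as mf:
        for rec in records:
            pssm_path = outdir / "pssm" / f"{rec.id}.pssm"
            write_pssm(pssm_path, rec.sequence, rec.pssm)
            if rec.labels3 is not None:
                labels[rec.id] = rec.labels3
            mf.write(f"{rec.id}\t{outdir / 'proteins.fasta'}\t{pssm_path}\t"
                     f"{rec.labels3 or ''}\n")
    write_labels(outdir / "labels.tsv", labels)
    return outdir
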