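"""Per-bin majority-vote SVM ensembles with length routing.

A full model holds one ensemble per length bin.  Each ensemble consists
of ``t`` RBF-kernel support vector machines, classifier ``j`` trained on
the projection of the bin's residue feature vectors onto subspace
``S_j``.  A query protein is routed by its length to exactly one bin's
ensemble; each residue then receives ``t`` hard votes and the majority
class wins, ties resolved by the fixed priority C > H > E (coil being
the most frequent state in globular proteins).

Default SVM hyperparameters are ``C = 0.9956`` and ``gamma = 0.065``
with one-vs-one multiclass decomposition (the libsvm scheme).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.svm import SVC

from .io import ProteinRecord, encode_windows
from .partition import PartitionScheme, assign_bin, default_scheme, partition_dataset
from .subspace import SubspaceSet, build_subspace_set

#: class order used for vote counting; earlier wins ties (C > H > E)
CLASS_PRIORITY = ("C", "H", "E")
_CLASS_CODE = {c: i for i, c in enumerate(CLASS_PRIORITY)}


@dataclass(frozen=True)
class BaseClassifierConfig:
    """Hyperparameters of one base SVM."""

    kernel: str = "rbf"
    C: float = 0.9956
    gamma: float = 0.065

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")

    def make(self) -> SVC:
        # SVC predicts via libsvm's internal one-vs-one vote
        return SVC(kernel=self.kernel, C=self.C, gamma=self.gamma,
                   cache_size=256)


def majority_vote(votes: Sequence[str]) -> str:
    """Majority class of a list of H/E/C votes; ties go C > H > E."""
    if len(votes) == 0:
        raise ValueError("empty vote list")
    counts = np.zeros(len(CLASS_PRIORITY), dtype=int)
    for v in votes:
        counts[_CLASS_CODE[v]] += 1
    return CLASS_PRIORITY[int(np.argmax(counts))]


def _vote_labels(pred_stack: np.ndarray) -> np.ndarray:
    """Vectorized majority vote over a ``(t, n)`` array of class labels."""
    t, n = pred_stack.shape
    codes = np.empty((t, n), dtype=np.int64)
    for c, code in _CLASS_CODE.items():
        codes[pred_stack == c] = code
    counts = np.zeros((len(CLASS_PRIORITY), n), dtype=np.int64)
    for code in range(len(CLASS_PRIORITY)):
        counts[code] = (codes == code).sum(axis=0)
    # argmax returns the first maximal row, matching the C > H > E priority
    winners = np.argmax(counts, axis=0)
    return np.asarray(CLASS_PRIORITY, dtype=object)[winners]


def _derive_seed(master: int, *key: int) -> int:
    """Deterministic 31-bit child seed from a master seed and a key path."""
    ss = np.random.SeedSequence([int(master), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def stratified_residue_sample(y: np.ndarray, cap: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-stratified sample of exactly ``min(cap, n)``
    residues, allocated proportionally to class frequencies."""
    n = len(y)
    if cap >= n:
        return np.arange(n)
    classes, class_counts = np.unique(y, return_counts=True)
    exact = cap * class_counts / n
    alloc = np.floor(exact).astype(int)
    # hand remaining slots to the largest fractional parts
    remainder = cap - alloc.sum()
    order = np.argsort(-(exact - alloc))
    alloc[order[:remainder]] += 1
    picked = []
    for cls, k in zip(classes, alloc):
        idx = np.flatnonzero(y == cls)
        picked.append(rng.choice(idx, size=k, replace=False))
    return np.sort(np.concatenate(picked))


@dataclass
class EnsembleModel:
    """``t`` trained base classifiers and their subspaces for one bin."""

    bin_index: int
    subspaces: SubspaceSet
    classifiers: list[SVC]

    @property
    def t(self) -> int:
        return self.subspaces.t

    def predict_features(self, features: np.ndarray) -> np.ndarray:
        """Majority-vote labels for an ``(n, n_features)`` matrix."""
        preds = np.empty((self.t, features.shape[0]), dtype=object)
        for j, clf in enumerate(self.classifiers):
            preds[j] = clf.predict(self.subspaces.project(features, j))
        return _vote_labels(preds)


def stack_bin_features(records: Sequence[ProteinRecord], w: int,
                       scaling: str) -> tuple[np.ndarray, np.ndarray]:
    """Encode and stack all residues of a bin into (X, y)."""
    xs, ys = [], []
    for rec in records:
        if rec.labels3 is None:
            raise ValueError(f"protein {rec.id!r} has no labels")
        xs.append(encode_windows(rec.pssm, w=w, scaling=scaling))
        ys.append(np.array(list(rec.labels3), dtype=object))
    return np.vstack(xs), np.concatenate(ys)


def train_ensemble(records: Sequence[ProteinRecord],
                   subspaces: SubspaceSet,
                   cfg: BaseClassifierConfig = BaseClassifierConfig(),
                   residue_cap: Optional[int] = None,
                   seed: int = 0,
                   w: int = 13,
                   scaling: str = "sigmoid",
                   bin_index: int = 1) -> EnsembleModel:
    """Train the ``t`` base classifiers of one bin.

    Each classifier is fit on the projection of the bin's residues onto
    its own subspace; with ``residue_cap`` set, each classifier draws
    its own class-stratified sample of exactly that many residues
    (independent samples add ensemble diversity on top of the subspace
    projections).
    """
    if len(records) == 0:
        raise ValueError(f"bin {bin_index}: no training proteins")
    X, y = stack_bin_features(records, w=w, scaling=scaling)
    present = set(y.tolist())
    missing = [c for c in CLASS_PRIORITY if c not in present]
    if missing:
        raise ValueError(
            f"bin {bin_index}: class(es) {missing} absent from the training "
            f"residues; every H/E/C class must be represented"
        )
    classifiers = []
    for j in range(subspaces.t):
        if residue_cap is not None and residue_cap < len(y):
            rng = np.random.default_rng(_derive_seed(seed, bin_index, j))
            idx = stratified_residue_sample(y, residue_cap, rng)
            Xj, yj = X[idx], y[idx]
        else:
            Xj, yj = X, y
        clf = cfg.make()
        clf.fit(subspaces.project(Xj, j), yj)
        classifiers.append(clf)
    return EnsembleModel(bin_index=bin_index, subspaces=subspaces,
                         classifiers=classifiers)


@dataclass
class PSRSMModel:
    """Partition scheme plus one trained ensemble per length bin."""

    scheme: PartitionScheme
    ensembles: list[EnsembleModel]
    w: int = 13
    scaling: str = "sigmoid"
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ensembles) != self.scheme.k:
            raise ValueError(
                f"{len(self.ensembles)} ensembles for a {self.scheme.k}-bin "
                f"scheme"
            )

    @property
    def t(self) -> int:
        return self.ensembles[0].t

    def route(self, record: ProteinRecord) -> int:
        """1-based bin index the record's length routes to."""
        return assign_bin(record.length, self.scheme)

    def predict(self, record: ProteinRecord) -> str:
        """Predict the H/E/C string of one protein via its routed bin."""
        if record.pssm is None:
            raise ValueError(f"protein {record.id!r} has no PSSM")
        ens = self.ensembles[self.route(record) - 1]
        feats = encode_windows(record.pssm, w=self.w, scaling=self.scaling)
        return "".join(ens.predict_features(feats))

    def predict_many(self, records: Sequence[ProteinRecord]) -> dict[str, str]:
        return {rec.id: self.predict(rec) for rec in records}


def train_psrsm(records: Sequence[ProteinRecord],
                scheme: Optional[PartitionScheme] = None,
                t: int = 12,
                r: int = 160,
                cfg: BaseClassifierConfig = BaseClassifierConfig(),
                residue_cap: Optional[int] = None,
                seed: int = 0,
                w: int = 13,
                scaling: str = "sigmoid") -> PSRSMModel:
    """Train the full length-routed model: one ensemble per bin.

    Every bin must receive at least one labeled protein; use a coarser
    scheme (fewer breakpoints) if the training set does not span all
    default bins.  Each bin gets its own subspace set and seed stream.
    """
    if scheme is None:
        scheme = default_scheme()
    bins = partition_dataset(records, scheme)
    empty = [i + 1 for i, b in enumerate(bins) if not b]
    if empty:
        raise ValueError(
            f"empty length bin(s) {empty}: every bin needs at least one "
            f"training protein (merge bins with a coarser scheme)"
        )
    pool_size = 20 * (w // 2)
    ensembles = []
    counts = {}
    for i, bin_records in enumerate(bins, start=1):
        subs = build_subspace_set(t=t, r=r,
                                  seed=_derive_seed(seed, i, 1_000_003),
                                  pool_size=pool_size)
        ens = train_ensemble(bin_records, subs, cfg=cfg,
                             residue_cap=residue_cap, seed=seed, w=w,
                             scaling=scaling, bin_index=i)
        ensembles.append(ens)
        counts[str(i)] = int(sum(rec.length for rec in bin_records))
    return PSRSMModel(scheme=scheme, ensembles=ensembles, w=w,
                      scaling=scaling, seed=seed,
                      metadata={"residues_per_bin": counts,
                                "config": {"t": t, "r": r, "C": cfg.C,
                                           "gamma": cfg.gamma,
                                           "residue_cap": residue_cap}})


# ---------------------------------------------------------------------------
# persistence: model.json + one joblib file per base classifier
# ---------------------------------------------------------------------------

def save_model(model: PSRSMModel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "breakpoints": list(model.scheme.breakpoints),
        "w": model.w,
        "scaling": model.scaling,
        "seed": model.seed,
        "metadata": model.metadata,
        "ensembles": [
            {"bin_index": ens.bin_index,
             "subspaces": json.loads(ens.subspaces.to_json())}
            for ens in model.ensembles
        ],
    }
    with open(directory / "model.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    for ens in model.ensembles:
        for j, clf in enumerate(ens.classifiers):
            joblib.dump(clf, directory / f"svm_bin{ens.bin_index}_{j}.joblib")


def load_model(directory) -> PSRSMModel:
    directory = Path(directory)
    with open(directory / "model.json") as fh:
        manifest = json.load(fh)
    ensembles = []
    for entry in manifest["ensembles"]:
        subs = SubspaceSet.from_json(json.dumps(entry["subspaces"]))
        clfs = [joblib.load(directory / f"svm_bin{entry['bin_index']}_{j}.joblib")
                for j in range(subs.t)]
        ensembles.append(EnsembleModel(bin_index=entry["bin_index"],
                                       subspaces=subs, classifiers=clfs))
    return PSRSMModel(scheme=PartitionScheme(tuple(manifest["breakpoints"])),
                      ensembles=ensembles, w=manifest["w"],
                      scaling=manifest["scaling"], seed=manifest["seed"],
                      metadata=manifest.get("metadata", {}))
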