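import numpy as np
import pytest

import psrsm
from psrsm.ensemble import (BaseClassifierConfig, EnsembleModel, PSRSMModel,
                            load_model, majority_vote, save_model,
                            stack_bin_features, stratified_residue_sample,
                            train_ensemble, train_psrsm)
from psrsm.io import encode_windows
from psrsm.partition import PartitionScheme
from psrsm.subspace import build_subspace_set


class TestMajorityVote:
    def test_strict_majority(self):
        assert majority_vote(list("H" * 7 + "E" * 3 + "C" * 2)) == "H"

    def test_tie_resolved_by_priority(self):
        # C > H > E: with C absent, a 6-6 H/E tie goes to H
        assert majority_vote(list("H" * 6 + "E" * 6)) == "H"
        assert majority_vote(list("C" * 4 + "H" * 4 + "E" * 4)) == "C"
        assert majority_vote(["E", "C"]) == "C"

    def test_unanimity(self):
        assert majority_vote(["C"] * 12) == "C"

    def test_empty_votes_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])


class TestStratifiedSampling:
    def test_cap_hit_exactly_with_proportional_classes(self, rng):
        y = np.array(list("H" * 5000 + "E" * 3000 + "C" * 2000), dtype=object)
        idx = stratified_residue_sample(y, 1000, rng)
        assert len(idx) == 1000
        assert len(set(idx.tolist())) == 1000
        picked = y[idx]
        assert int((picked == "H").sum()) == 500
        assert int((picked == "E").sum()) == 300
        assert int((picked == "C").sum()) == 200

    def test_cap_above_population_returns_everything(self, rng):
        y = np.array(list("HEC" * 5), dtype=object)
        assert len(stratified_residue_sample(y, 100, rng)) == 15


class TestTrainEnsemble:
    def test_base_classifiers_learn_separable_signal(self, separable_bin):
        train, holdout = separable_bin
        subs = build_subspace_set(t=4, r=80, seed=1)
        ens = train_ensemble(train, subs, residue_cap=600, seed=2)
        X, y = stack_bin_features(holdout, w=13, scaling="sigmoid")
        for j, clf in enumerate(ens.classifiers):
            acc = float((clf.predict(subs.project(X, j)) == y).mean())
            assert acc > 0.8, f"base classifier {j} accuracy {acc:.3f}"

    def test_missing_class_named_in_error(self, separable_bin):
        train, _ = separable_bin
        stripped = [psrsm.ProteinRecord(id=r.id, sequence=r.sequence,
                                        pssm=r.pssm,
                                        labels3=r.labels3.replace("E", "C"))
                    for r in train[:4]]
        subs = build_subspace_set(t=4, r=80, seed=1)
        with pytest.raises(ValueError, match="'E'"):
            train_ensemble(stripped, subs)

    def test_empty_bin_rejected(self):
        subs = build_subspace_set(t=4, r=80, seed=1)
        with pytest.raises(ValueError, match="no training proteins"):
            train_ensemble([], subs)

    def test_same_seed_identical_predictions(self, separable_bin):
        train, holdout = separable_bin
        subs = build_subspace_set(t=4, r=80, seed=1)
        X, _ = stack_bin_features(holdout, w=13, scaling="sigmoid")
        a = train_ensemble(train, subs, residue_cap=500, seed=11)
        b = train_ensemble(train, subs, residue_cap=500, seed=11)
        assert np.array_equal(a.predict_features(X), b.predict_features(X))

    def test_prediction_invariant_to_classifier_order(self, separable_bin):
        train, holdout = separable_bin
        subs = build_subspace_set(t=4, r=80, seed=1)
        ens = train_ensemble(train, subs, residue_cap=500, seed=11)
        X, _ = stack_bin_features(holdout[:3], w=13, scaling="sigmoid")
        base = ens.predict_features(X)
        perm = [2, 0, 3, 1]
        permuted = EnsembleModel(
            bin_index=ens.bin_index,
            subspaces=type(ens.subspaces)(
                t=ens.subspaces.t, d=ens.subspaces.d, seed=ens.subspaces.seed,
                pool_size=ens.subspaces.pool_size,
                left_subsets=[ens.subspaces.left_subsets[p] for p in perm],
                right_subsets=[ens.subspaces.right_subsets[p] for p in perm]),
            classifiers=[ens.classifiers[p] for p in perm])
        assert np.array_equal(permuted.predict_features(X), base)


class TestPSRSMModel:
    def test_structure_and_routing(self, two_bin_model):
        model, _, test = two_bin_model
        assert len(model.ensembles) == 2
        assert sum(len(e.classifiers) for e in model.ensembles) == 2 * 4
        for rec in test:
            expected_bin = 1 if rec.length <= 100 else 2
            assert model.route(rec) == expected_bin
            assert len(model.predict(rec)) == rec.length

    def test_predictions_accurate_on_matched_data(self, two_bin_model):
        model, _, test = two_bin_model
        report = psrsm.evaluate(model.predict_many(test),
                                {r.id: r.labels3 for r in test})
        assert report.average_q3 > 80.0

    def test_empty_bin_listed_in_error(self, separable_bin):
        train, _ = separable_bin  # all proteins shorter than 100
        with pytest.raises(ValueError, match=r"\[2\]"):
            train_psrsm(train, scheme=PartitionScheme((100.0,)), t=4, r=80)

    def test_save_load_round_trip_preserves_predictions(self, two_bin_model,
                                                        tmp_path):
        model, _, test = two_bin_model
        save_model(model, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        assert loaded.scheme == model.scheme
        for rec in test[:4]:
            assert loaded.predict(rec) == model.predict(rec)

    def test_training_twice_identical_artifacts(self, separable_bin,
                                                tmp_path):
        train, _ = separable_bin
        kwargs = dict(scheme=PartitionScheme(()), t=4, r=80,
                      residue_cap=400, seed=17)
        save_model(train_psrsm(train, **kwargs), tmp_path / "a")
        save_model(train_psrsm(train, **kwargs), tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_missing_pssm_rejected(self, two_bin_model):
        model, _, _ = two_bin_model
        rec = psrsm.ProteinRecord(id="x", sequence="AAAA",
                                  pssm=np.zeros((4, 20)))
        object.__setattr__(rec, "pssm", None)
        with pytest.raises(ValueError, match="PSSM"):
            model.predict(rec)


def test_vote_counts_conserved_per_residue(separable_bin):
    """Every residue receives exactly t votes that sum across classes."""
    train, holdout = separable_bin
    subs = build_subspace_set(t=4, r=80, seed=1)
    ens = train_ensemble(train[:10], subs, residue_cap=300, seed=0)
    X, _ = stack_bin_features(holdout[:2], w=13, scaling="sigmoid")
    votes = np.stack([clf.predict(subs.project(X, j))
                      for j, clf in enumerate(ens.classifiers)])
    assert votes.shape[0] == subs.t
    per_residue = [(votes[:, i] == "H").sum() + (votes[:, i] == "E").sum()
                   + (votes[:, i] == "C").sum() for i in range(X.shape[0])]
    assert all(v == subs.t for v in per_residue)
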