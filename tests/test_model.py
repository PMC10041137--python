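from types import SimpleNamespace

import numpy as np
import pytest

import ddiscreen as dd
from ddiscreen.catalog import load_catalog
from ddiscreen.chem_io import DrugRecord
from ddiscreen.errors import DataError, ProvenanceError
from ddiscreen.model import (
    GoldStandardPair,
    assemble_features,
    load_model,
    process_predictions,
    read_gold_standard,
    save_model,
    write_gold_standard,
)
from ddiscreen.similarity import ReferenceSet, build_ssp, fit_reducer, reduce


@pytest.fixture(scope="module")
def toy_featurization():
    drugs = [
        DrugRecord(f"d{i}", f"n{i}", s)
        for i, s in enumerate(["CCO", "c1ccccc1", "CC(=O)O", "CCN(C)C", "CCCCC", "CCOC"])
    ]
    ref = ReferenceSet.from_drugs(drugs)
    M = np.stack([build_ssp(d, ref).values for d in drugs])
    reducer = fit_reducer(M, k=3)
    return drugs, ref, reducer


class TestAssembleFeatures:
    def test_length_is_twice_k(self, toy_featurization):
        drugs, ref, reducer = toy_featurization
        f = assemble_features((drugs[0], drugs[1]), ref, reducer)
        assert f.vector.shape == (6,)

    def test_swapping_swaps_halves_exactly(self, toy_featurization):
        drugs, ref, reducer = toy_featurization
        fab = assemble_features((drugs[0], drugs[1]), ref, reducer)
        fba = assemble_features((drugs[1], drugs[0]), ref, reducer)
        np.testing.assert_array_equal(fab.vector[:3], fba.vector[3:])
        np.testing.assert_array_equal(fab.vector[3:], fba.vector[:3])

    def test_same_molecule_rewritten_gives_identical_halves(self, toy_featurization):
        drugs, ref, reducer = toy_featurization
        rewritten = DrugRecord("dX", "ethanol-again", "OCC")
        f = assemble_features((drugs[0], rewritten), ref, reducer)
        np.testing.assert_allclose(f.vector[:3], f.vector[3:], atol=1e-12)

    def test_matches_reduce_of_ssp_composition(self, toy_featurization):
        drugs, ref, reducer = toy_featurization
        f = assemble_features((drugs[2], drugs[3]), ref, reducer)
        expected = np.concatenate(
            [reduce(build_ssp(drugs[2], ref), reducer), reduce(build_ssp(drugs[3], ref), reducer)]
        )
        np.testing.assert_allclose(f.vector, expected)


class TestTraining:
    def test_same_seed_gives_byte_identical_weights(self, tiny_dataset):
        ds = tiny_dataset
        cfg = dd.TrainConfig(seed=9, max_epochs=8)
        pairs = ds.pairs[:120]
        m1 = dd.train(pairs, ds.drugs, config=cfg, negatives=ds.negatives[:20])
        m2 = dd.train(pairs, ds.drugs, config=cfg, negatives=ds.negatives[:20])
        assert m1.params.to_flat().tobytes() == m2.params.to_flat().tobytes()

    def test_degenerate_single_type_recovered(self):
        drugs = dd.generate_molecules(16, seed=21)
        pairs = [
            GoldStandardPair(drugs[i].drug_id, drugs[j].drug_id, frozenset({1}))
            for i in range(8)
            for j in range(8, 16)
        ]
        with pytest.warns(UserWarning, match="fewer than 2"):
            model = dd.train(pairs, drugs, config=dd.TrainConfig(seed=0, max_epochs=40))
        held_out = (drugs[0], drugs[9])
        scores = dd.predict_pair(model, *held_out)
        assert scores[0] > model.threshold

    def test_unresolvable_drug_id_is_data_error(self, tiny_dataset):
        ds = tiny_dataset
        bad = [GoldStandardPair("nope_a", "nope_b", frozenset({3}))]
        with pytest.raises(DataError, match="nope_a"):
            dd.train(ds.pairs + bad, ds.drugs)

    def test_unknown_type_id_is_data_error(self, tiny_dataset):
        ds = tiny_dataset
        bad = [GoldStandardPair(ds.drugs[0].drug_id, ds.drugs[1].drug_id, frozenset({999}))]
        with pytest.raises(DataError, match="999"):
            dd.train(bad + ds.pairs, ds.drugs)


class TestPrediction:
    def test_score_vector_length_and_range(self, tiny_model, tiny_dataset):
        a, b = tiny_dataset.drugs[:2]
        scores = dd.predict_pair(tiny_model, a, b)
        assert scores.shape == (tiny_model.catalog_size,)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_repeated_calls_identical(self, tiny_model, tiny_dataset):
        a, b = tiny_dataset.drugs[2], tiny_dataset.drugs[5]
        np.testing.assert_array_equal(
            dd.predict_pair(tiny_model, a, b), dd.predict_pair(tiny_model, a, b)
        )

    def test_planted_type_scores_separate_rule_pairs(self, tiny_model, tiny_dataset):
        """Mean planted-type score over rule-satisfying pairs exceeds non-satisfying."""
        from ddiscreen.synthetic import rule_applies

        ds = tiny_dataset
        rule = ds.rules[0]
        col = rule.type_id - 1
        pos_scores, neg_scores = [], []
        index = {d.drug_id: d for d in ds.drugs}
        for p in ds.pairs[:60] + [
            GoldStandardPair(a, b, frozenset({1})) for a, b in ds.negatives[:20]
        ]:
            a, b = index[p.drug_a_id], index[p.drug_b_id]
            s = max(dd.predict_pair(tiny_model, a, b)[col], dd.predict_pair(tiny_model, b, a)[col])
            (pos_scores if rule_applies(rule, a.smiles, b.smiles) else neg_scores).append(s)
        assert pos_scores and neg_scores
        assert np.mean(pos_scores) > np.mean(neg_scores)

    def test_provenance_mismatch_refused(self, tiny_model):
        other = ReferenceSet.from_drugs(
            [DrugRecord("x", "x", "CCO"), DrugRecord("y", "y", "CCC")]
        )
        a, b = tiny_model.reference.drugs[:2]
        with pytest.raises(ProvenanceError, match="digest"):
            dd.predict_pair(tiny_model, a, b, reference=other)


@pytest.fixture(scope="module")
def small_catalog(tmp_path_factory):
    p = tmp_path_factory.mktemp("cat") / "cat.csv"
    p.write_text(
        "type_id,keyword,template,directional\n"
        "1,dir-type,{A} affects {B},true\n"
        "2,sym-type,{A} with {B} interact,false\n"
    )
    return load_catalog(p)


class TestProcessPredictions:
    def _model(self, threshold=0.5):
        return SimpleNamespace(threshold=threshold)

    def _drugs(self):
        return DrugRecord("a", "DrugA", "CCO"), DrugRecord("b", "DrugB", "CCC")

    def test_all_below_threshold_empty(self, small_catalog):
        a, b = self._drugs()
        out = process_predictions(
            np.array([0.2, 0.1]), np.array([0.3, 0.4]), self._model(), small_catalog, a, b
        )
        assert out == []

    def test_nondirectional_takes_max_and_emits_once(self, small_catalog):
        a, b = self._drugs()
        out = process_predictions(
            np.array([0.0, 0.9]), np.array([0.0, 0.4]), self._model(), small_catalog, a, b
        )
        assert len(out) == 1
        assert out[0].type_id == 2 and out[0].score == 0.9

    def test_nondirectional_call_invariant_under_swap(self, small_catalog):
        a, b = self._drugs()
        out_ab = process_predictions(
            np.array([0.0, 0.4]), np.array([0.0, 0.9]), self._model(), small_catalog, a, b
        )
        out_ba = process_predictions(
            np.array([0.0, 0.9]), np.array([0.0, 0.4]), self._model(), small_catalog, b, a
        )
        assert [(r.type_id, r.score) for r in out_ab] == [(r.type_id, r.score) for r in out_ba]

    def test_directional_both_orders_two_records_distinct_sentences(self, small_catalog):
        a, b = self._drugs()
        out = process_predictions(
            np.array([0.8, 0.0]), np.array([0.7, 0.0]), self._model(), small_catalog, a, b
        )
        assert len(out) == 2
        assert out[0].sentence != out[1].sentence
        assert out[0].sentence == "DrugA affects DrugB"
        assert out[1].sentence == "DrugB affects DrugA"

    def test_records_sorted_by_descending_score(self, small_catalog):
        a, b = self._drugs()
        out = process_predictions(
            np.array([0.6, 0.95]), np.array([0.7, 0.2]), self._model(), small_catalog, a, b
        )
        scores = [r.score for r in out]
        assert scores == sorted(scores, reverse=True)

    def test_no_emitted_record_below_threshold(self, small_catalog):
        a, b = self._drugs()
        out = process_predictions(
            np.array([0.49, 0.51]), np.array([0.5, 0.1]), self._model(), small_catalog, a, b
        )
        assert all(r.score >= 0.5 for r in out)


class TestSerialization:
    def test_gold_standard_roundtrip(self, tmp_path, tiny_dataset):
        path = tmp_path / "gold.csv"
        pairs = tiny_dataset.pairs[:10]
        write_gold_standard(pairs, path)
        assert read_gold_standard(path) == pairs

    def test_model_bundle_roundtrip_preserves_predictions(self, tmp_path, tiny_model, tiny_dataset):
        save_model(tiny_model, tmp_path / "bundle")
        again = load_model(tmp_path / "bundle")
        a, b = tiny_dataset.drugs[1], tiny_dataset.drugs[7]
        np.testing.assert_array_equal(
            dd.predict_pair(tiny_model, a, b), dd.predict_pair(again, a, b)
        )
        assert again.reference_digest == tiny_model.reference_digest
        assert again.catalog_size == tiny_model.catalog_size
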