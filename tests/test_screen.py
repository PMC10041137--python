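import numpy as np
import pytest

import ddiscreen as dd
from ddiscreen.catalog import load_catalog
from ddiscreen.errors import ConfigurationError
from ddiscreen.model import PredictionRecord
from ddiscreen.screen import (
    ScreenResult,
    compare_reference_lists,
    read_prediction_table,
    read_screen_table,
    screen_panel,
    summarize,
    write_report,
    write_screen_table,
)


def rec(d, q, t, score=0.9):
    return PredictionRecord(q, d, t, score, f"{q}/{d}/{t}")


@pytest.fixture()
def toy_result():
    records = [rec("d1", "q1", 3), rec("d1", "q1", 89), rec("d2", "q2", 89)]
    return ScreenResult(records=records, panel_size=5, queries=["q1", "q2"])


class TestSummarize:
    def test_hand_counted_toy(self, toy_result):
        s = summarize(toy_result)
        assert s.total_ddis == 3
        assert len(s.interacting_union) == 2
        assert s.max_types_per_pair == 2
        assert s.per_drug_type_counts == {("d1", "q1"): 2, ("d2", "q2"): 1}
        assert s.per_type_drug_counts == {(3, "q1"): 1, (89, "q1"): 1, (89, "q2"): 1}

    def test_duplicate_triples_counted_once(self):
        records = [rec("d1", "q1", 3, 0.9), rec("d1", "q1", 3, 0.6)]
        s = summarize(ScreenResult(records=records, panel_size=3, queries=["q1"]))
        assert s.total_ddis == 1

    def test_empty_result_all_zero(self):
        s = summarize(ScreenResult(records=[], panel_size=4, queries=["q1"]))
        assert s.total_ddis == 0 and s.interacting_union == set() and s.max_types_per_pair == 0

    def test_union_is_union_of_per_query_sets(self, toy_result):
        s = summarize(toy_result)
        assert s.interacting_union == set().union(*s.interacting_by_query.values())

    def test_double_counting_identity(self, toy_result):
        """Per-query: sum over drugs of type counts equals sum over types of drug counts."""
        s = summarize(toy_result)
        for q in s.interacting_by_query:
            lhs = sum(c for (d, qq), c in s.per_drug_type_counts.items() if qq == q)
            rhs = sum(c for (t, qq), c in s.per_type_drug_counts.items() if qq == q)
            assert lhs == rhs

    def test_total_equals_sum_of_per_drug_counts(self, toy_result):
        s = summarize(toy_result)
        assert s.total_ddis == sum(s.per_drug_type_counts.values())


class TestCompareReferenceLists:
    NAME_MAP = {f"Drug {i}": f"d{i}" for i in range(1, 9)}

    def _summary(self, interacting):
        res = ScreenResult(
            records=[rec(d, "q1", 3) for d in interacting], panel_size=8, queries=["q1"]
        )
        return summarize(res)

    def test_fully_contained_list_is_100_percent(self):
        s = self._summary(["d1", "d2"])
        rep = compare_reference_lists(s, ["Drug 1", "Drug 2"], self.NAME_MAP)
        assert rep.fraction == 100.0

    def test_empty_reference_list_flagged(self):
        rep = compare_reference_lists(self._summary(["d1"]), [], self.NAME_MAP)
        assert rep.n_ref == 0 and rep.fraction is None

    def test_hand_counted_fraction(self):
        # 8 names, 5 match the panel, 4 of those interact -> 4/8 = 50.0%
        s = self._summary(["d1", "d2", "d3", "d4"])
        names = ["Drug 1", "Drug 2", "Drug 3", "Drug 4", "Drug 5", "Nope A", "Nope B", "Nope C"]
        rep = compare_reference_lists(s, names, self.NAME_MAP)
        assert rep.n_ref == 8
        assert rep.n_matched_to_panel == 5
        assert rep.n_predicted_interacting == 4
        assert rep.fraction == 50.0
        assert rep.unmatched == ["Nope A", "Nope B", "Nope C"]

    def test_matching_is_case_and_whitespace_insensitive(self):
        s = self._summary(["d1"])
        rep = compare_reference_lists(s, ["  drug   1 "], self.NAME_MAP)
        assert rep.n_predicted_interacting == 1


class TestScreenPanel:
    def test_bound_and_threshold_soundness(self, tiny_model, tiny_dataset):
        queries = tiny_dataset.drugs[:2]
        panel = tiny_dataset.drugs[2:12]
        result = screen_panel(tiny_model, queries, panel)
        assert all(r.score >= tiny_model.threshold for r in result.records)
        assert result.panel_size == 10

    def test_self_pairing_excluded_only_on_matching_id(self, tiny_model, tiny_dataset):
        q = tiny_dataset.drugs[0]
        clone = dd.DrugRecord("clone_id", q.name, q.smiles)
        result = screen_panel(tiny_model, [q], [q, clone])
        assert all(r.partner_id != q.drug_id for r in result.records)
        # structurally identical drug under a different id is still evaluated
        assert {r.partner_id for r in result.records} <= {"clone_id"}

    def test_empty_panel_warns(self, tiny_model, tiny_dataset):
        with pytest.warns(UserWarning, match="empty panel"):
            result = screen_panel(tiny_model, tiny_dataset.drugs[:1], [])
        assert result.records == [] and result.panel_size == 0

    def test_empty_queries_rejected(self, tiny_model, tiny_dataset):
        with pytest.raises(ConfigurationError):
            screen_panel(tiny_model, [], tiny_dataset.drugs[:3])


class TestScreenTableIO:
    def test_roundtrip(self, tmp_path, toy_result):
        path = tmp_path / "screen.tsv"
        write_screen_table(toy_result, path)
        again = read_screen_table(path)
        assert [(r.query_id, r.partner_id, r.type_id) for r in again.records] == [
            (r.query_id, r.partner_id, r.type_id) for r in toy_result.records
        ]
        assert again.panel_size == toy_result.panel_size
        assert again.queries == toy_result.queries

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("a\tb\n1\t2\n")
        with pytest.raises(ConfigurationError):
            read_screen_table(p)


class TestPredictionTableIngestion:
    """Summary layer over an externally produced (synthetic) prediction table."""

    def _write_csv(self, path):
        path.write_text(
            "drug,component,type_id\n"
            "Amlodipine,ritonavir,89\n"
            "Amlodipine,ritonavir,3\n"
            "Metformin,nirmatrelvir,58\n"
        )

    def test_csv_ingestion_counts(self, tmp_path):
        p = tmp_path / "preds.csv"
        self._write_csv(p)
        catalog = load_catalog()
        result = read_prediction_table(p, catalog, panel_size=10)
        s = summarize(result)
        assert s.total_ddis == 3
        assert s.interacting_union == {"Amlodipine", "Metformin"}
        assert s.interacting_by_query == {
            "ritonavir": {"Amlodipine"},
            "nirmatrelvir": {"Metformin"},
        }
        assert s.panel_size == 10

    def test_xlsx_ingestion_matches_csv(self, tmp_path):
        import pandas as pd

        p_csv = tmp_path / "preds.csv"
        self._write_csv(p_csv)
        p_xlsx = tmp_path / "preds.xlsx"
        pd.read_csv(p_csv).to_excel(p_xlsx, index=False)
        catalog = load_catalog()
        s_csv = summarize(read_prediction_table(p_csv, catalog))
        s_xlsx = summarize(read_prediction_table(p_xlsx, catalog))
        assert s_csv.per_drug_type_counts == s_xlsx.per_drug_type_counts

    def test_unknown_type_rejected(self, tmp_path):
        p = tmp_path / "preds.csv"
        p.write_text("drug,component,type_id\nX,q,999\n")
        with pytest.raises(ConfigurationError, match="999"):
            read_prediction_table(p, load_catalog())


def test_write_report_emits_tables_and_headline(tmp_path, toy_result):
    s = summarize(toy_result)
    write_report(s, tmp_path / "report")
    import json

    headline = json.loads((tmp_path / "report" / "headline.json").read_text())
    assert headline["total_ddis"] == 3
    assert headline["n_interacting_drugs"] == 2
    assert (tmp_path / "report" / "per_drug_type_counts.tsv").exists()
    assert (tmp_path / "report" / "per_type_drug_counts.tsv").exists()
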