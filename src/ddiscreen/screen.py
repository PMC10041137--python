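"""Panel screening and summary analytics.

Screens query drugs (e.g. the two Paxlovid components) against a
prescription-drug panel: every (query, panel drug) pair is scored in both
orders and post-processed into call records.  The summary layer counts a
DDI as a distinct (panel drug, query, type) triple — the convention under
which per-drug type counts, per-type drug counts and the total DDI count
are mutually consistent — and compares the interacting set against
external reference drug lists (e.g. agency-published interaction lists).

An ingestion adapter reads an externally produced prediction table
(drug name / query component / type id) into the same ScreenResult
container, so the summary layer also works on published prediction tables
without the model that generated them.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .catalog import Catalog, render_sentence
from .chem_io import DrugRecord
from .errors import ConfigurationError, StructureError
from .model import PredictionRecord, TrainedModel, predict_features, process_predictions


@dataclass
class ScreenResult:
    records: list[PredictionRecord]
    panel_size: int
    queries: list[str]
    failed: list[tuple[str, str]] = field(default_factory=list)  # (drug_id, reason)


@dataclass
class ScreenSummary:
    per_drug_type_counts: dict[tuple[str, str], int]  # (panel drug, query) -> #types
    per_type_drug_counts: dict[tuple[int, str], int]  # (type, query) -> #drugs
    interacting_by_query: dict[str, set[str]]
    interacting_union: set[str]
    total_ddis: int
    max_types_per_pair: int
    panel_size: int


@dataclass
class OverlapReport:
    n_ref: int
    n_matched_to_panel: int
    n_predicted_interacting: int
    fraction: float | None  # percent to 0.1; None (flagged) when n_ref == 0
    unmatched: list[str] = field(default_factory=list)


def screen_panel(
    model: TrainedModel, queries: list[DrugRecord], panel: list[DrugRecord]
) -> ScreenResult:
    """Score every (query, panel drug) pair in both orders and post-process.

    Self-pairs (matching drug_id) are skipped; a panel drug identical in
    structure but with a different id is still evaluated.  Panel drugs whose
    structures cannot be fingerprinted are reported in ``failed``, never
    silently dropped.
    """
    if not queries:
        raise ConfigurationError("queries must be non-empty")
    if not panel:
        warnings.warn("empty panel: returning an empty screen result")
        return ScreenResult(records=[], panel_size=0, queries=[q.drug_id for q in queries])
    failed: list[tuple[str, str]] = []
    ok_panel: list[DrugRecord] = []
    for d in panel:
        try:
            feats_one = predict_features(model, [d])  # validates fingerprintability
            ok_panel.append(d)
        except StructureError as exc:
            failed.append((d.drug_id, str(exc)))
    feats = predict_features(model, queries + ok_panel)
    records: list[PredictionRecord] = []
    for q in queries:
        fq = feats[q.drug_id]
        others = [d for d in ok_panel if d.drug_id != q.drug_id]
        if others:
            X_ab = np.stack([np.concatenate([fq, feats[d.drug_id]]) for d in others])
            X_ba = np.stack([np.concatenate([feats[d.drug_id], fq]) for d in others])
            S_ab = nn.predict_proba(model.params, X_ab)
            S_ba = nn.predict_proba(model.params, X_ba)
            for i, d in enumerate(others):
                records.extend(
                    process_predictions(S_ab[i], S_ba[i], model, model.catalog, q, d)
                )
    records.sort(key=lambda r: (-r.score, r.query_id, r.partner_id, r.type_id, r.sentence))
    return ScreenResult(
        records=records, panel_size=len(panel), queries=[q.drug_id for q in queries], failed=failed
    )


def summarize(result: ScreenResult) -> ScreenSummary:
    """Count distinct (panel drug, query, type) triples and interacting sets."""
    triples = {(r.partner_id, r.query_id, r.type_id) for r in result.records}
    per_drug_type: dict[tuple[str, str], int] = {}
    per_type_drug: dict[tuple[int, str], int] = {}
    by_query: dict[str, set[str]] = {q: set() for q in result.queries}
    for d, q, t in triples:
        per_drug_type[(d, q)] = per_drug_type.get((d, q), 0) + 1
        per_type_drug[(t, q)] = per_type_drug.get((t, q), 0) + 1
        by_query.setdefault(q, set()).add(d)
    union: set[str] = set().union(*by_query.values()) if by_query else set()
    return ScreenSummary(
        per_drug_type_counts=per_drug_type,
        per_type_drug_counts=per_type_drug,
        interacting_by_query=by_query,
        interacting_union=union,
        total_ddis=len(triples),
        max_types_per_pair=max(per_drug_type.values(), default=0),
        panel_size=result.panel_size,
    )


def _normalize_name(name: str) -> str:
    return " ".join(name.split()).casefold()


def compare_reference_lists(
    summary: ScreenSummary, ref_list: list[str], name_map: dict[str, str]
) -> OverlapReport:
    """Overlap of an external drug-name list with the predicted interacting set.

    ``name_map`` maps panel drug names to drug_ids.  Matching is exact,
    case-insensitive after whitespace normalization; unmatched names are
    reported, never fuzzily matched.  ``fraction`` is the percentage of the
    reference list predicted to interact with at least one query, to 0.1%.
    """
    norm_map = {_normalize_name(k): v for k, v in name_map.items()}
    if not ref_list:
        return OverlapReport(0, 0, 0, fraction=None)
    matched_ids: list[str] = []
    unmatched: list[str] = []
    for name in ref_list:
        key = _normalize_name(name)
        if key in norm_map:
            matched_ids.append(norm_map[key])
        else:
            unmatched.append(name)
    n_interacting = len({i for i in matched_ids if i in summary.interacting_union})
    fraction = round(100.0 * n_interacting / len(ref_list), 1)
    return OverlapReport(
        n_ref=len(ref_list),
        n_matched_to_panel=len(set(matched_ids)),
        n_predicted_interacting=n_interacting,
        fraction=fraction,
        unmatched=unmatched,
    )


# ---------------------------------------------------------------------------
# screen-table I/O and the external prediction-table ingestion adapter
# ---------------------------------------------------------------------------

SCREEN_COLUMNS = ["query_id", "partner_id", "type_id", "score", "sentence"]


def write_screen_table(result: ScreenResult, path: str | Path) -> None:
    """TSV with columns query_id, partner_id, type_id, score, sentence."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(SCREEN_COLUMNS + ["panel_size", "queries"])
        meta = [result.panel_size, ";".join(result.queries)]
        for r in result.records:
            w.writerow([r.query_id, r.partner_id, r.type_id, f"{r.score:.6f}", r.sentence] + meta)
            meta = ["", ""]
        if not result.records:
            pass


def read_screen_table(path: str | Path) -> ScreenResult:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"screen table missing columns {missing}")
    records = [
        PredictionRecord(
            row["query_id"], row["partner_id"], int(row["type_id"]), float(row["score"]), row["sentence"]
        )
        for _, row in df.iterrows()
    ]
    if "panel_size" in df.columns and len(df) and str(df.iloc[0]["panel_size"]).strip():
        panel_size = int(df.iloc[0]["panel_size"])
        queries = [q for q in str(df.iloc[0]["queries"]).split(";") if q]
    else:
        panel_size = len({r.partner_id for r in records})
        queries = sorted({r.query_id for r in records})
    return ScreenResult(records=records, panel_size=panel_size, queries=queries)


def read_prediction_table(
    path: str | Path,
    catalog: Catalog,
    *,
    drug_col: str = "drug",
    query_col: str = "component",
    type_col: str = "type_id",
    score_col: str | None = None,
    panel_size: int | None = None,
) -> ScreenResult:
    """Ingest an externally produced prediction table into a ScreenResult.

    Accepts CSV/TSV/XLSX with one row per predicted (panel drug, query
    component, DDI type).  Scores default to 1.0 when the source table
    carries calls without probabilities.  This lets the summary layer run on
    published prediction tables directly.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep="\t" if path.suffix.lower() == ".tsv" else ",")
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in (drug_col, query_col, type_col):
        if col not in df.columns:
            raise ConfigurationError(f"prediction table missing column {col!r}; has {list(df.columns)}")
    records = []
    for _, row in df.iterrows():
        tid = int(row[type_col])
        if tid not in catalog:
            raise ConfigurationError(f"prediction table row has unknown type_id {tid}")
        score = float(row[score_col]) if score_col and score_col in df.columns else 1.0
        a, b = str(row[query_col]).strip(), str(row[drug_col]).strip()
        records.append(
            PredictionRecord(a, b, tid, score, render_sentence(catalog, tid, a, b))
        )
    queries = sorted({r.query_id for r in records})
    return ScreenResult(
        records=records,
        panel_size=panel_size if panel_size is not None else len({r.partner_id for r in records}),
        queries=queries,
    )


def write_report(
    summary: ScreenSummary,
    out_dir: str | Path,
    overlaps: dict[str, OverlapReport] | None = None,
) -> None:
    """Write per-drug and per-type count tables (TSV) plus headline JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "per_drug_type_counts.tsv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["panel_drug", "query", "n_types"])
        for (d, q), c in sorted(summary.per_drug_type_counts.items()):
            w.writerow([d, q, c])
    with open(out_dir / "per_type_drug_counts.tsv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["type_id", "query", "n_drugs"])
        for (t, q), c in sorted(summary.per_type_drug_counts.items()):
            w.writerow([t, q, c])
    headline = {
        "panel_size": summary.panel_size,
        "n_interacting_drugs": len(summary.interacting_union),
        "n_interacting_by_query": {
            q: len(s) for q, s in sorted(summary.interacting_by_query.items())
        },
        "total_ddis": summary.total_ddis,
        "max_types_per_pair": summary.max_types_per_pair,
    }
    if overlaps:
        headline["reference_overlaps"] = {
            name: {
                "n_ref": o.n_ref,
                "n_matched_to_panel": o.n_matched_to_panel,
                "n_predicted_interacting": o.n_predicted_interacting,
                "fraction_percent": o.fraction,
                "unmatched": o.unmatched,
            }
            for name, o in overlaps.items()
        }
    (out_dir / "headline.json").write_text(json.dumps(headline, indent=1, sort_keys=True))
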