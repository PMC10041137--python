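"""Alternative-drug proposals for interaction-flagged panel drugs.

A flagged drug's alternatives must satisfy two criteria: (1) the candidate
has no predicted DDI with any query component, and (2) it shares a
mechanism of action (MoA) with the flagged drug.  MoA equality is exact
string match after case/whitespace normalization; multi-valued MoA cells
are split on '|' and ';' (the Repurposing Hub export dialect).  No ontology
mapping is attempted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .chem_io import DrugRecord
from .errors import ConfigurationError
from .screen import ScreenSummary


@dataclass(frozen=True)
class MoAAnnotation:
    name: str
    moa: str
    target: str | None = None

    def __post_init__(self):
        if not self.name.strip():
            raise ConfigurationError("MoA annotation with empty drug name")


@dataclass(frozen=True)
class AlternativeSuggestion:
    flagged_drug: str  # panel drug name
    alternatives: tuple[str, ...]  # panel drug names, deterministic order
    moa: str  # shared normalized MoA string(s), '|'-joined
    n_alternatives: int


@dataclass
class AlternativesReport:
    suggestions: list[AlternativeSuggestion]
    unannotated: list[str]  # flagged drugs with no MoA annotation


def _norm(s: str) -> str:
    return " ".join(s.split()).casefold()


def _split_moa(cell: str) -> set[str]:
    parts = cell.replace(";", "|").split("|")
    return {_norm(p) for p in parts if p.strip()}


def read_moa_table(path: str | Path) -> list[MoAAnnotation]:
    """CSV/TSV with columns (name, moa[, target])."""
    path = Path(path)
    delim = "\t" if path.suffix.lower() == ".tsv" else ","
    out: list[MoAAnnotation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or not {"name", "moa"} <= {f.lower() for f in reader.fieldnames}:
            raise ConfigurationError("MoA table must have columns (name, moa[, target])")
        for row in reader:
            row = {k.lower(): (v or "") for k, v in row.items()}
            out.append(MoAAnnotation(row["name"].strip(), row["moa"].strip(), row.get("target") or None))
    return out


def find_alternatives(
    summary: ScreenSummary,
    panel: list[DrugRecord],
    moa_table: list[MoAAnnotation],
    within_class: bool = False,
) -> AlternativesReport:
    """Propose panel-internal alternatives for every flagged drug.

    Candidates are panel drugs with zero predicted DDIs against every query
    (criterion 1) sharing at least one normalized MoA string with the
    flagged drug (criterion 2).  ``within_class`` additionally requires a
    matching ``drug_class`` column value.  Flagged drugs with no MoA
    annotation are reported separately, never silently skipped.
    """
    by_id = {d.drug_id: d for d in panel}
    moa_by_name: dict[str, set[str]] = {}
    for ann in moa_table:
        if ann.moa:
            moa_by_name.setdefault(_norm(ann.name), set()).update(_split_moa(ann.moa))
    # criterion 1 candidate pool: panel drugs outside the interacting union
    safe = [d for d in panel if d.drug_id not in summary.interacting_union]
    flagged_ids = sorted(summary.interacting_union & set(by_id))
    suggestions: list[AlternativeSuggestion] = []
    unannotated: list[str] = []
    for fid in flagged_ids:
        flagged = by_id[fid]
        moas = moa_by_name.get(_norm(flagged.name), set())
        if not moas:
            unannotated.append(flagged.name)
            continue
        shared_moas: set[str] = set()
        alts: list[str] = []
        for cand in safe:
            cand_moas = moa_by_name.get(_norm(cand.name), set())
            common = moas & cand_moas
            if not common:
                continue
            if within_class and (
                flagged.drug_class is None
                or cand.drug_class is None
                or _norm(flagged.drug_class) != _norm(cand.drug_class)
            ):
                continue
            alts.append(cand.name)
            shared_moas |= common
        suggestions.append(
            AlternativeSuggestion(
                flagged_drug=flagged.name,
                alternatives=tuple(sorted(alts)),
                moa="|".join(sorted(shared_moas)) if shared_moas else "|".join(sorted(moas)),
                n_alternatives=len(alts),
            )
        )
    return AlternativesReport(suggestions=suggestions, unannotated=sorted(unannotated))


def write_alternatives(report: AlternativesReport, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["flagged_drug", "n_alternatives", "alternatives", "shared_moa"])
        for s in report.suggestions:
            w.writerow([s.flagged_drug, s.n_alternatives, ";".join(s.alternatives), s.moa])
        for name in report.unannotated:
            w.writerow([name, "", "", "UNANNOTATED"])
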