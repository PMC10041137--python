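"""The DDI-type catalogue: 113 interaction categories with sentence templates.

Each type has a short keyword (e.g. "the decreased metabolism of a drug"),
a sentence template with ``{A}`` and ``{B}`` slots, and a directionality
flag: for directional types (serum-concentration and metabolism changes)
swapping the two drugs changes the meaning of the sentence; for mutual-
activity types (e.g. increased QTc-prolonging activities) it does not.

Templates are data, not code: the bundled fixture anchors 14 well-known
keywords and marks the remaining entries provisional, so a complete
catalogue table can be dropped in without code changes.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import CatalogError

BUNDLED_CATALOG_SIZE = 113

_TRUTHY = {"true", "1", "yes", "y", "t"}


@dataclass(frozen=True)
class DDIType:
    type_id: int
    keyword: str
    template: str
    directional: bool
    provisional: bool = False

    def __post_init__(self):
        if "{A}" not in self.template or "{B}" not in self.template:
            raise CatalogError(
                f"type {self.type_id}: template must contain both {{A}} and {{B}} slots"
            )
        if self.directional and (
            self.template.count("{A}") != 1 or self.template.count("{B}") != 1
        ):
            raise CatalogError(
                f"type {self.type_id}: directional template must contain each slot exactly once"
            )


@dataclass(frozen=True)
class Catalog:
    entries: dict[int, DDIType]
    source: str

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, type_id: int) -> bool:
        return type_id in self.entries

    def __getitem__(self, type_id: int) -> DDIType:
        if type_id not in self.entries:
            raise CatalogError(f"unknown DDI type_id {type_id}")
        return self.entries[type_id]

    def type_ids(self) -> list[int]:
        return sorted(self.entries)


def _validate(entries: list[DDIType], source: str) -> Catalog:
    seen: set[int] = set()
    for e in entries:
        if e.type_id < 1:
            raise CatalogError(f"type_id {e.type_id} out of range (must be >= 1)")
        if e.type_id in seen:
            raise CatalogError(f"duplicate type_id {e.type_id} in catalogue {source}")
        seen.add(e.type_id)
    if seen != set(range(1, max(seen) + 1)):
        missing = sorted(set(range(1, max(seen) + 1)) - seen)
        raise CatalogError(f"catalogue ids not contiguous from 1; missing {missing[:10]}")
    return Catalog(entries={e.type_id: e for e in entries}, source=source)


def _entry_from_mapping(row: dict) -> DDIType:
    try:
        type_id = int(row["type_id"])
    except (KeyError, ValueError) as exc:
        raise CatalogError(f"bad or missing type_id in row {row!r}") from exc
    directional = row.get("directional", "false")
    if isinstance(directional, str):
        directional = directional.strip().lower() in _TRUTHY
    provisional = row.get("provisional", "false")
    if isinstance(provisional, str):
        provisional = provisional.strip().lower() in _TRUTHY
    return DDIType(
        type_id=type_id,
        keyword=row["keyword"].strip(),
        template=row["template"].strip(),
        directional=bool(directional),
        provisional=bool(provisional),
    )


def load_catalog(path: str | Path | None = None) -> Catalog:
    """Load a catalogue from CSV or JSON; ``None`` loads the bundled 113-type fixture."""
    if path is None:
        ref = resources.files("ddiscreen").joinpath("data/ddi_types.csv")
        with resources.as_file(ref) as p:
            return load_catalog(p)
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(rows, list):
            raise CatalogError("JSON catalogue must be a list of row objects")
    else:
        delim = "\t" if path.suffix.lower() == ".tsv" else ","
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh, delimiter=delim))
    if not rows:
        raise CatalogError(f"empty catalogue file {path}")
    required = {"type_id", "keyword", "template", "directional"}
    if not required <= set(rows[0]):
        raise CatalogError(
            f"catalogue must have columns {sorted(required)}; found {sorted(rows[0])}"
        )
    return _validate([_entry_from_mapping(r) for r in rows], source=str(path))


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["type_id", "keyword", "template", "directional", "provisional"])
        for tid in catalog.type_ids():
            e = catalog.entries[tid]
            w.writerow(
                [e.type_id, e.keyword, e.template, str(e.directional).lower(), str(e.provisional).lower()]
            )


def render_sentence(catalog: Catalog, type_id: int, drug_a: str, drug_b: str) -> str:
    """Substitute the two drug names into the type's sentence template.

    For directional types, (A, B) and (B, A) produce sentences with different
    meanings; rendering never yields the identical string when the names differ.
    """
    entry = catalog[type_id]
    return entry.template.replace("{A}", drug_a).replace("{B}", drug_b)
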