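"""Drug structure tables and circular fingerprints.

Drugs enter the pipeline as (drug_id, name, smiles) rows in a CSV/TSV table.
Every SMILES is canonicalized with RDKit on ingestion; rows that do not parse
are rejected with a reason rather than silently dropped.  Fingerprints are
binary Morgan (ECFP-style) circular fingerprints: a pure function of the
canonical structure, so any SMILES writing of the same molecule yields
identical bits.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .errors import ConfigurationError, StructureError

RDLogger.DisableLog("rdApp.*")

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 2048

REQUIRED_COLUMNS = ("drug_id", "name", "smiles")
OPTIONAL_COLUMNS = ("drug_class", "indication", "moa")


@dataclass(frozen=True)
class DrugRecord:
    """One drug: identifier, display name, canonical SMILES, optional annotations."""

    drug_id: str
    name: str
    smiles: str
    drug_class: str | None = None
    indication: str | None = None
    moa: str | None = None
    extra: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class Rejection:
    """One rejected input row: 1-based data row number, id (if any) and reason."""

    row: int
    drug_id: str
    reason: str


@dataclass(frozen=True)
class BitFingerprint:
    """Fixed-length binary substructure-environment vector.

    Two fingerprints are comparable only if ``n_bits`` and ``radius`` match.
    ``bits`` is an immutable uint8 0/1 array of length ``n_bits``.
    """

    bits: np.ndarray
    n_bits: int
    radius: int

    def __post_init__(self):
        if self.bits.shape != (self.n_bits,):
            raise ValueError("bits length must equal n_bits")
        self.bits.setflags(write=False)

    def popcount(self) -> int:
        return int(self.bits.sum())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BitFingerprint)
            and self.n_bits == other.n_bits
            and self.radius == other.radius
            and bool(np.array_equal(self.bits, other.bits))
        )

    def __hash__(self):
        return hash((self.n_bits, self.radius, self.bits.tobytes()))


def canonicalize_smiles(smiles: str) -> str:
    """Return RDKit canonical SMILES, or raise StructureError if unparseable."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def _dialect_for(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    if fmt not in {"csv", "tsv"}:
        raise ConfigurationError(f"unknown table format {fmt!r} (expected csv or tsv)")
    return "\t" if fmt == "tsv" else ","


def read_drug_table(
    path: str | Path, format: str | None = None
) -> tuple[list[DrugRecord], list[Rejection]]:
    """Read a drug table with at least (drug_id, name, smiles) columns.

    Column matching is case-insensitive; extra columns are preserved in
    ``DrugRecord.extra``.  Returns accepted records (input order preserved,
    SMILES canonicalized) and the list of rejected rows with reasons.
    Duplicate drug_ids among otherwise-valid rows raise ConfigurationError
    naming the offending row numbers.
    """
    path = Path(path)
    delim = _dialect_for(path, format)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delim)
        rows = list(reader)
    if not rows:
        return [], []
    header = [h.strip().lower() for h in rows[0]]
    missing = [c for c in REQUIRED_COLUMNS if c not in header]
    if missing:
        raise ConfigurationError(
            f"missing required column(s) {missing} in {path.name}; found {header}"
        )
    idx = {c: header.index(c) for c in header}
    records: list[DrugRecord] = []
    rejections: list[Rejection] = []
    seen: dict[str, int] = {}
    for rownum, row in enumerate(rows[1:], start=1):
        if not any(cell.strip() for cell in row):
            continue
        get = lambda c: row[idx[c]].strip() if c in idx and idx[c] < len(row) else ""
        drug_id, name, smiles = get("drug_id"), get("name"), get("smiles")
        if not drug_id:
            rejections.append(Rejection(rownum, drug_id, "empty drug_id"))
            continue
        if not name:
            rejections.append(Rejection(rownum, drug_id, "empty name"))
            continue
        try:
            canonical = canonicalize_smiles(smiles)
        except StructureError:
            rejections.append(Rejection(rownum, drug_id, "unparseable SMILES"))
            continue
        if drug_id in seen:
            raise ConfigurationError(
                f"duplicated drug_id {drug_id!r} on rows {seen[drug_id]} and {rownum}"
            )
        seen[drug_id] = rownum
        extra = {
            c: row[idx[c]].strip()
            for c in header
            if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS and idx[c] < len(row)
        }
        records.append(
            DrugRecord(
                drug_id=drug_id,
                name=name,
                smiles=canonical,
                drug_class=get("drug_class") or None,
                indication=get("indication") or None,
                moa=get("moa") or None,
                extra=extra,
            )
        )
    return records, rejections


def read_sdf(path: str | Path) -> tuple[list[DrugRecord], list[Rejection]]:
    """Read an SDF file, mapping each record's title line to drug_id and name."""
    path = Path(path)
    records: list[DrugRecord] = []
    rejections: list[Rejection] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier, start=1):
        if mol is None:
            rejections.append(Rejection(i, "", "unparseable SDF record"))
            continue
        title = (mol.GetProp("_Name") if mol.HasProp("_Name") else "") or f"mol_{i}"
        records.append(
            DrugRecord(drug_id=title, name=title, smiles=Chem.MolToSmiles(mol))
        )
    return records, rejections


def write_rejections(rejections: list[Rejection], path: str | Path) -> None:
    """Write a rejection report as TSV (row, drug_id, reason)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["row", "drug_id", "reason"])
        for r in rejections:
            w.writerow([r.row, r.drug_id, r.reason])


def write_drug_table(records: list[DrugRecord], path: str | Path) -> None:
    """Write records back out as CSV with the standard columns."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["drug_id", "name", "smiles", "drug_class", "indication", "moa"])
        for r in records:
            w.writerow(
                [r.drug_id, r.name, r.smiles, r.drug_class or "", r.indication or "", r.moa or ""]
            )


def fingerprint(
    record: DrugRecord | str,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> BitFingerprint:
    """Binary Morgan fingerprint of a drug (or a bare SMILES string).

    Deterministic in the molecule: equivalent SMILES writings canonicalize to
    the same structure and therefore the same bits.
    """
    if radius < 0:
        raise ConfigurationError("radius must be >= 0")
    if n_bits < 64:
        raise ConfigurationError("n_bits must be >= 64")
    if isinstance(record, DrugRecord):
        smiles, drug_id = record.smiles, record.drug_id
    else:
        smiles, drug_id = record, None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}", drug_id=drug_id)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    return BitFingerprint(bits=bits, n_bits=n_bits, radius=radius)
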