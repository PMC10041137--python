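"""Synthetic molecules, planted DDI labels and screening fixtures.

Real gold-standard DDI corpora are license-restricted, so every pipeline
stage is exercised on generated data instead.  Molecules are assembled from
a small SMILES grammar (alkyl/cyclohexyl/phenyl scaffolds decorated with
chemically meaningful motifs: a tertiary amine, a carboxylic acid, a
chlorine).  DDI labels are then planted by substructure rules — a pair gets
a type iff the rule's SMARTS motifs occur in its drugs — optionally
corrupted by independent label flips.

The motifs span multiple atoms with distinct radius-1/2 environments, so a
radius-2 circular fingerprint separates motif carriers from non-carriers
and the planted rules are learnable from structural similarity profiles by
construction.  Because the generator also evaluates its own rules by brute
force, fixtures come with exact expected screening counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem_io import DrugRecord
from .errors import ConfigurationError, DataError
from .model import GoldStandardPair

# fragment appended during generation, SMARTS used to detect it
MOTIFS: dict[str, tuple[str, str]] = {
    "tertiary_amine": ("CN(C)C", "[NX3]([#6])([#6])[#6]"),
    "carboxyl": ("C(=O)O", "[CX3](=O)[OX2H1]"),
    "chloro": ("Cl", "[Cl]"),
    "phenyl": ("c1ccccc1", "c1ccccc1"),
}

DEFAULT_MOTIF_NAMES = ("tertiary_amine", "carboxyl", "chloro", "phenyl")


@dataclass(frozen=True)
class PlantedRule:
    """Substructure rule that decides one DDI type for a pair.

    The rule fires when one drug matches ``trigger`` and the other matches
    ``partner_trigger`` (``None`` means the partner is unconstrained), in
    either order.  ``noise_rate`` flips the planted label independently.
    """

    type_id: int
    trigger: str
    partner_trigger: str | None = None
    noise_rate: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.noise_rate < 0.5):
            raise ConfigurationError("noise_rate must be in [0, 0.5)")
        if Chem.MolFromSmarts(self.trigger) is None:
            raise ConfigurationError(f"bad trigger SMARTS {self.trigger!r}")
        if self.partner_trigger is not None and Chem.MolFromSmarts(self.partner_trigger) is None:
            raise ConfigurationError(f"bad partner SMARTS {self.partner_trigger!r}")


def matches(smiles: str, smarts: str) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    patt = Chem.MolFromSmarts(smarts)
    return mol is not None and mol.HasSubstructMatch(patt)


def rule_applies(rule: PlantedRule, smiles_a: str, smiles_b: str) -> bool:
    """Deterministic (noise-free) rule evaluation on a pair, order-invariant."""
    ta, tb = matches(smiles_a, rule.trigger), matches(smiles_b, rule.trigger)
    if rule.partner_trigger is None:
        return ta or tb
    pa = matches(smiles_a, rule.partner_trigger)
    pb = matches(smiles_b, rule.partner_trigger)
    return (ta and pb) or (tb and pa)


def default_rules(noise_rate: float = 0.0) -> list[PlantedRule]:
    """Three rules over distinct catalogue types, mixing single- and two-motif triggers."""
    amine = MOTIFS["tertiary_amine"][1]
    carboxyl = MOTIFS["carboxyl"][1]
    return [
        PlantedRule(89, trigger=amine, noise_rate=noise_rate),
        PlantedRule(3, trigger=carboxyl, noise_rate=noise_rate),
        PlantedRule(53, trigger=carboxyl, partner_trigger=amine, noise_rate=noise_rate),
    ]


def screen_rules(noise_rate: float = 0.0) -> list[PlantedRule]:
    """Partner-conditioned rules for the screening fixture.

    Every rule requires a motif on *both* sides, so each query drug flags
    only a structure-dependent subset of the panel and a motif-poor subset
    stays interaction-free — the pool the alternatives stage draws from.
    """
    amine = MOTIFS["tertiary_amine"][1]
    carboxyl = MOTIFS["carboxyl"][1]
    phenyl = MOTIFS["phenyl"][1]
    cyclohexyl = "[CX4]1[CX4][CX4][CX4][CX4][CX4]1"
    return [
        PlantedRule(89, trigger=amine, partner_trigger=phenyl, noise_rate=noise_rate),
        PlantedRule(3, trigger=carboxyl, partner_trigger=cyclohexyl, noise_rate=noise_rate),
        PlantedRule(53, trigger=carboxyl, partner_trigger=amine, noise_rate=noise_rate),
    ]


def _compose_smiles(rng: np.random.Generator, motif_flags: dict[str, bool]) -> str:
    """Assemble one valid SMILES from the grammar; motif fragments per flags."""
    parts = ["C" * int(rng.integers(1, 11))]
    if motif_flags.get("chloro"):
        parts.append("(Cl)")
    if rng.random() < 0.5:
        parts.append("(C)C")  # methyl branch
    if rng.random() < 0.5:
        parts.append("C1CCCCC1")  # cyclohexyl scaffold
    if rng.random() < 0.4:
        parts.append("O")  # ether linker
    if motif_flags.get("phenyl"):
        parts.append(MOTIFS["phenyl"][0])
    spacer = int(rng.integers(0, 7))
    if spacer:
        parts.append("C" * spacer)
    if motif_flags.get("tertiary_amine"):
        parts.append(MOTIFS["tertiary_amine"][0])
    if motif_flags.get("carboxyl"):
        parts.append(MOTIFS["carboxyl"][0])  # must stay terminal
    return "".join(parts)


def generate_molecules(
    n: int,
    seed: int,
    motif_fraction: float = 0.4,
    motifs: tuple[str, ...] = DEFAULT_MOTIF_NAMES,
    id_prefix: str = "D",
) -> list[DrugRecord]:
    """Generate ``n`` distinct valid molecules, seeded.

    Each motif in ``motifs`` is planted independently with probability
    ``motif_fraction``.  Output is a pure function of the arguments.
    """
    if n < 2:
        raise ConfigurationError("need n >= 2 molecules")
    if not (0.0 <= motif_fraction <= 1.0):
        raise ConfigurationError("motif_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    records: list[DrugRecord] = []
    attempts = 0
    while len(records) < n:
        attempts += 1
        if attempts > 200 * n:
            raise ConfigurationError(
                f"could not generate {n} distinct molecules (grammar exhausted)"
            )
        flags = {m: bool(rng.random() < motif_fraction) for m in motifs}
        smiles = _compose_smiles(rng, flags)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # grammar should always parse; guard anyway
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        i = len(records) + 1
        records.append(
            DrugRecord(drug_id=f"{id_prefix}{i:04d}", name=f"synthomycin-{i:03d}", smiles=canonical)
        )
    return records


def plant_labels(
    drugs: list[DrugRecord],
    rules: list[PlantedRule],
    n_pairs: int,
    seed: int,
) -> tuple[list[GoldStandardPair], list[tuple[str, str]]]:
    """Sample distinct pairs and label them by the rules, with label-flip noise.

    Returns (labelled pairs, explicit negative pairs).  A pair is labelled
    with a rule's type iff the rule applies, then each label is flipped
    independently with that rule's noise_rate.  Pairs are sampled without
    replacement from all unordered pairs.
    """
    if not rules:
        raise ConfigurationError("rules must be non-empty")
    n = len(drugs)
    total = n * (n - 1) // 2
    if n_pairs > total:
        raise DataError(f"requested {n_pairs} pairs but only {total} distinct pairs exist")
    for rule in rules:
        if not any(matches(d.smiles, rule.trigger) for d in drugs):
            raise DataError(f"rule for type {rule.type_id}: trigger matches no generated molecule")
    rng = np.random.default_rng(seed)
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    chosen = rng.choice(total, size=n_pairs, replace=False)
    chosen.sort()
    pair_index = [all_pairs[int(lin)] for lin in chosen]
    positives: list[GoldStandardPair] = []
    negatives: list[tuple[str, str]] = []
    for i, j in pair_index:
        a, b = drugs[i], drugs[j]
        if rng.random() < 0.5:
            a, b = b, a
        labels = set()
        for rule in rules:
            lab = rule_applies(rule, a.smiles, b.smiles)
            if rule.noise_rate and rng.random() < rule.noise_rate:
                lab = not lab
            if lab:
                labels.add(rule.type_id)
        if labels:
            positives.append(GoldStandardPair(a.drug_id, b.drug_id, frozenset(labels)))
        else:
            negatives.append((a.drug_id, b.drug_id))
    return positives, negatives


# ---------------------------------------------------------------------------
# presets and the end-to-end screening fixture
# ---------------------------------------------------------------------------

_MOA_POOL = (
    "beta blocker",
    "calcium channel blocker",
    "angiotensin receptor antagonist",
    "ACE inhibitor",
    "HMG-CoA reductase inhibitor",
    "SSRI",
    "sulfonylurea",
    "proton pump inhibitor",
)


@dataclass(frozen=True)
class Preset:
    n_drugs: int
    n_pairs: int
    noise_rate: float
    motif_fraction: float = 0.4


PRESETS: dict[str, Preset] = {
    "tiny": Preset(n_drugs=40, n_pairs=200, noise_rate=0.0),
    "default": Preset(n_drugs=200, n_pairs=2000, noise_rate=0.05),
    "screen": Preset(n_drugs=120, n_pairs=2000, noise_rate=0.0, motif_fraction=0.35),
}


@dataclass
class LabelledDataset:
    drugs: list[DrugRecord]
    rules: list[PlantedRule]
    pairs: list[GoldStandardPair]
    negatives: list[tuple[str, str]]


def make_dataset(preset: str, seed: int) -> LabelledDataset:
    """Generate a preset-sized planted-rule gold standard."""
    if preset not in PRESETS:
        raise ConfigurationError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[preset]
    rules = default_rules(noise_rate=p.noise_rate)
    if preset == "tiny":
        rules = rules[:2]
    drugs = generate_molecules(p.n_drugs, seed=seed, motif_fraction=p.motif_fraction)
    pairs, negatives = plant_labels(drugs, rules, n_pairs=p.n_pairs, seed=seed + 1)
    return LabelledDataset(drugs=drugs, rules=rules, pairs=pairs, negatives=negatives)


@dataclass
class ScreenFixture:
    """Everything needed for an end-to-end screen with known answers."""

    queries: list[DrugRecord]
    panel: list[DrugRecord]
    train_drugs: list[DrugRecord]
    train_pairs: list[GoldStandardPair]
    train_negatives: list[tuple[str, str]]
    rules: list[PlantedRule]
    moa_table: list[tuple[str, str]]  # (drug name, moa)
    ref_lists: dict[str, list[str]]
    expected: dict = field(default_factory=dict)


def _expected_counts(
    queries: list[DrugRecord], panel: list[DrugRecord], rules: list[PlantedRule]
) -> dict:
    """Brute-force rule evaluation over every (query, panel drug) pair."""
    per_drug_type: dict[tuple[str, str], set[int]] = {}
    for q in queries:
        for d in panel:
            if d.drug_id == q.drug_id:
                continue
            tids = {r.type_id for r in rules if rule_applies(r, q.smiles, d.smiles)}
            if tids:
                per_drug_type[(d.drug_id, q.drug_id)] = tids
    interacting_by_query = {
        q.drug_id: {d for (d, qq) in per_drug_type if qq == q.drug_id} for q in queries
    }
    union = set().union(*interacting_by_query.values()) if interacting_by_query else set()
    per_type_drug = {}
    for (d, q), tids in per_drug_type.items():
        for t in tids:
            per_type_drug.setdefault((t, q), set()).add(d)
    return {
        "per_drug_type_counts": {k: len(v) for k, v in per_drug_type.items()},
        "per_type_drug_counts": {k: len(v) for k, v in per_type_drug.items()},
        "interacting_by_query": interacting_by_query,
        "interacting_union": union,
        "total_ddis": sum(len(v) for v in per_drug_type.values()),
    }


def make_screen_fixture(seed: int) -> ScreenFixture:
    """Queries, panel, MoA and reference-list tables with brute-force expected answers.

    Two query drugs emulate the protease-inhibitor/CYP-inhibitor pairing: one
    motif-free scaffold and one tertiary-amine carrier.  The panel and extra
    filler drugs form the training universe, so the screen probes pairs whose
    drugs (though not necessarily the pairs themselves) were seen in training,
    mirroring screening against a model trained on a broad drug corpus.
    """
    p = PRESETS["screen"]
    rules = screen_rules(noise_rate=p.noise_rate)
    queries = [
        DrugRecord("Q_NMV", "nirmatrelvir-like", Chem.CanonSmiles("CCCC1CCCCC1")),
        DrugRecord("Q_RTV", "ritonavir-like", Chem.CanonSmiles("CCc1ccccc1CCN(C)C")),
    ]
    rng = np.random.default_rng(seed)
    panel = generate_molecules(
        50, seed=seed + 10, motif_fraction=p.motif_fraction, id_prefix="P"
    )
    filler = generate_molecules(
        p.n_drugs - len(panel) - len(queries),
        seed=seed + 20,
        motif_fraction=p.motif_fraction,
        id_prefix="F",
    )
    train_drugs = queries + panel + filler
    pairs, negatives = plant_labels(train_drugs, rules, n_pairs=p.n_pairs, seed=seed + 30)
    expected = _expected_counts(queries, panel, rules)

    moa_table: list[tuple[str, str]] = []
    for d in panel:
        if rng.random() < 0.8:  # some panel drugs stay unannotated
            moa_table.append((d.name, _MOA_POOL[int(rng.integers(0, len(_MOA_POOL)))]))
    names = [d.name for d in panel]
    ref_lists = {
        "fda_like": sorted(rng.choice(names, size=16, replace=False).tolist()),
        "ema_like": sorted(rng.choice(names, size=20, replace=False).tolist()),
    }
    name_to_id = {d.name: d.drug_id for d in panel}
    for key in ref_lists:
        ids = {name_to_id[n] for n in ref_lists[key]}
        n_hit = len(ids & expected["interacting_union"])
        expected[f"{key}_fraction"] = 100.0 * n_hit / len(ref_lists[key])

    return ScreenFixture(
        queries=queries,
        panel=panel,
        train_drugs=train_drugs,
        train_pairs=pairs,
        train_negatives=negatives,
        rules=rules,
        moa_table=moa_table,
        ref_lists=ref_lists,
        expected=expected,
    )
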