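"""Multi-label DDI-type classifier over ordered drug pairs.

A pair (A, B) is featurized as reduce(SSP(A)) concatenated with
reduce(SSP(B)) — length 2k — and mapped to 113 independent per-type
probabilities.  Training is seeded end to end; the serialized bundle
records the featurization provenance (reference-set digest) so that a
model refuses features built against a different reference.

Raw score vectors for both pair orders are post-processed into calls:
scores are thresholded; directional types keep their order (each order can
yield its own sentence); non-directional types take the maximum over the
two orders and are emitted once.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .catalog import Catalog, load_catalog, render_sentence, write_catalog
from .chem_io import DrugRecord
from .errors import ConfigurationError, DataError, ProvenanceError
from .similarity import (
    Reducer,
    ReferenceSet,
    build_ssp,
    build_ssp_matrix,
    fit_reducer,
    load_reducer,
    load_reference,
    reduce,
    save_reducer,
    save_reference,
)

_MODEL_VERSION = 1


@dataclass(frozen=True)
class GoldStandardPair:
    """One labelled ordered pair from the gold-standard DDI table."""

    drug_a_id: str
    drug_b_id: str
    type_ids: frozenset[int]

    def __post_init__(self):
        if self.drug_a_id == self.drug_b_id:
            raise DataError(f"self-pair {self.drug_a_id!r} is not a valid gold-standard pair")


@dataclass(frozen=True)
class PairFeature:
    vector: np.ndarray
    drug_a_id: str
    drug_b_id: str

    def __post_init__(self):
        self.vector.setflags(write=False)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters; every field has a documented desk-scale default."""

    hidden_layers: tuple[int, ...] = (256, 256)
    k: int = 100
    radius: int = 2
    n_bits: int = 2048
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 15
    val_fraction: float = 0.1
    threshold: float = 0.5
    pos_weight_cap: float = 100.0
    seed: int = 0


@dataclass(frozen=True)
class PredictionRecord:
    query_id: str
    partner_id: str
    type_id: int
    score: float
    sentence: str


@dataclass
class TrainedModel:
    config: TrainConfig
    layer_sizes: list[int]
    params: nn.MLPParams
    threshold: float
    seed: int
    reference: ReferenceSet
    reducer: Reducer
    catalog: Catalog

    @property
    def reference_digest(self) -> str:
        return self.reference.digest

    @property
    def catalog_size(self) -> int:
        return len(self.catalog)


def assemble_features(
    pair: tuple[DrugRecord, DrugRecord], ref: ReferenceSet, reducer: Reducer
) -> PairFeature:
    """Concatenated reduced profiles of the ordered pair; length 2k.

    Swapping the pair swaps the two halves exactly.
    """
    a, b = pair
    va = reduce(build_ssp(a, ref), reducer)
    vb = reduce(build_ssp(b, ref), reducer)
    return PairFeature(vector=np.concatenate([va, vb]), drug_a_id=a.drug_id, drug_b_id=b.drug_id)


def _resolve(pairs: list[GoldStandardPair], drugs: list[DrugRecord]) -> dict[str, DrugRecord]:
    index = {d.drug_id: d for d in drugs}
    missing = sorted(
        {pid for p in pairs for pid in (p.drug_a_id, p.drug_b_id) if pid not in index}
    )
    if missing:
        raise DataError(f"gold-standard pairs reference unknown drug_id(s): {missing[:10]}")
    return index


def train(
    pairs: list[GoldStandardPair],
    drugs: list[DrugRecord],
    config: TrainConfig = TrainConfig(),
    catalog: Catalog | None = None,
    reference: ReferenceSet | None = None,
    negatives: list[tuple[str, str]] | None = None,
) -> TrainedModel:
    """Fit the featurization and the classifier on gold-standard pairs.

    The reference set defaults to the gold standard's drug universe (table
    order).  Each pair is augmented with its swapped order carrying the same
    label set; direction is applied downstream at post-processing.
    ``negatives`` are explicit interaction-free pairs (all-zero label rows).
    Same (pairs, drugs, config) always yields identical serialized weights.
    """
    if catalog is None:
        catalog = load_catalog()
    negatives = negatives or []
    if not pairs:
        raise DataError("no gold-standard pairs supplied")
    index = _resolve(pairs, drugs)
    neg_missing = sorted(
        {pid for ab in negatives for pid in ab if pid not in {d.drug_id for d in drugs}}
    )
    if neg_missing:
        raise DataError(f"negative pairs reference unknown drug_id(s): {neg_missing[:10]}")
    neg_index = {d.drug_id: d for d in drugs}
    for p in pairs:
        bad = [t for t in p.type_ids if t not in catalog]
        if bad:
            raise DataError(f"pair ({p.drug_a_id},{p.drug_b_id}) has unknown type ids {bad}")
    all_types = sorted({t for p in pairs for t in p.type_ids})
    if len(all_types) < 2:
        warnings.warn("gold standard contains fewer than 2 distinct DDI types")

    if reference is None:
        used = {pid for p in pairs for pid in (p.drug_a_id, p.drug_b_id)}
        used |= {pid for ab in negatives for pid in ab}
        ref_drugs = [d for d in drugs if d.drug_id in used]
        reference = ReferenceSet.from_drugs(ref_drugs, radius=config.radius, n_bits=config.n_bits)
    index.update({pid: neg_index[pid] for ab in negatives for pid in ab})

    ssp = build_ssp_matrix(list(reference.drugs), reference)
    k = min(config.k, ssp.shape[0] - 1, ssp.shape[1])
    if k < 1:
        raise ConfigurationError("reference set too small to fit a reducer")
    reducer = fit_reducer(ssp, k=k)

    reduced = {d.drug_id: row for d, row in zip(reference.drugs, reduce(ssp, reducer))}

    def feat(pid: str) -> np.ndarray:
        if pid in reduced:
            return reduced[pid]
        return reduce(build_ssp(index[pid], reference), reducer)

    n_types = len(catalog)
    n_rows = 2 * (len(pairs) + len(negatives))
    X = np.empty((n_rows, 2 * k))
    Y = np.zeros((n_rows, n_types))
    for i, p in enumerate(pairs):
        fa, fb = feat(p.drug_a_id), feat(p.drug_b_id)
        X[2 * i] = np.concatenate([fa, fb])
        X[2 * i + 1] = np.concatenate([fb, fa])
        for t in p.type_ids:
            Y[2 * i, t - 1] = 1.0
            Y[2 * i + 1, t - 1] = 1.0
    base = 2 * len(pairs)
    for i, (aid, bid) in enumerate(negatives):
        fa, fb = feat(aid), feat(bid)
        X[base + 2 * i] = np.concatenate([fa, fb])
        X[base + 2 * i + 1] = np.concatenate([fb, fa])

    pos = Y.sum(axis=0)
    neg = Y.shape[0] - pos
    with np.errstate(divide="ignore", invalid="ignore"):
        pos_weight = np.where(pos > 0, np.minimum(neg / np.maximum(pos, 1.0), config.pos_weight_cap), 1.0)

    layer_sizes = [2 * k, *config.hidden_layers, n_types]
    fit = nn.fit_mlp(
        X,
        Y,
        layer_sizes,
        seed=config.seed,
        pos_weight=pos_weight,
        lr=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        val_fraction=config.val_fraction,
    )
    return TrainedModel(
        config=replace(config, k=k),
        layer_sizes=layer_sizes,
        params=fit.params,
        threshold=config.threshold,
        seed=config.seed,
        reference=reference,
        reducer=reducer,
        catalog=catalog,
    )


def _check_provenance(model: TrainedModel, ref: ReferenceSet | None) -> None:
    if ref is not None and ref.digest != model.reference_digest:
        raise ProvenanceError(
            f"reference digest {ref.digest[:12]}… does not match the model's "
            f"{model.reference_digest[:12]}…"
        )


def predict_pair(
    model: TrainedModel,
    a: DrugRecord,
    b: DrugRecord,
    reference: ReferenceSet | None = None,
) -> np.ndarray:
    """Score vector over the catalogue for the ordered pair (a, b); values in [0, 1]."""
    _check_provenance(model, reference)
    f = assemble_features((a, b), model.reference, model.reducer)
    return nn.predict_proba(model.params, f.vector[None, :])[0]


def predict_features(model: TrainedModel, drugs: list[DrugRecord]) -> dict[str, np.ndarray]:
    """Reduced feature vector per drug, computed once for batch screening."""
    rows = reduce(build_ssp_matrix(drugs, model.reference), model.reducer)
    return {d.drug_id: row for d, row in zip(drugs, rows)}


def scores_from_features(
    model: TrainedModel, fa: np.ndarray, fb: np.ndarray
) -> np.ndarray:
    return nn.predict_proba(model.params, np.concatenate([fa, fb])[None, :])[0]


def process_predictions(
    scores_ab: np.ndarray,
    scores_ba: np.ndarray,
    model: TrainedModel,
    catalog: Catalog,
    drug_a: DrugRecord,
    drug_b: DrugRecord,
) -> list[PredictionRecord]:
    """Turn the two ordered score vectors into threshold-passing call records.

    Directional types: each order passing the threshold yields its own record
    and sentence.  Non-directional types: the maximum over the orders is
    taken and the pair is emitted once.  Records are sorted by descending
    score (ties broken by type id and order for stable output).
    """
    thr = model.threshold
    records: list[PredictionRecord] = []
    for pos, tid in enumerate(catalog.type_ids()):
        entry = catalog[tid]
        s_ab, s_ba = float(scores_ab[pos]), float(scores_ba[pos])
        if entry.directional:
            if s_ab >= thr:
                records.append(
                    PredictionRecord(
                        drug_a.drug_id, drug_b.drug_id, tid, s_ab,
                        render_sentence(catalog, tid, drug_a.name, drug_b.name),
                    )
                )
            if s_ba >= thr:
                records.append(
                    PredictionRecord(
                        drug_a.drug_id, drug_b.drug_id, tid, s_ba,
                        render_sentence(catalog, tid, drug_b.name, drug_a.name),
                    )
                )
        else:
            s = max(s_ab, s_ba)
            if s >= thr:
                records.append(
                    PredictionRecord(
                        drug_a.drug_id, drug_b.drug_id, tid, s,
                        render_sentence(catalog, tid, drug_a.name, drug_b.name),
                    )
                )
    records.sort(key=lambda r: (-r.score, r.type_id, r.sentence))
    return records


def predict_calls(
    model: TrainedModel, a: DrugRecord, b: DrugRecord
) -> list[PredictionRecord]:
    """Convenience: score both orders of (a, b) and post-process into calls."""
    s_ab = predict_pair(model, a, b)
    s_ba = predict_pair(model, b, a)
    return process_predictions(s_ab, s_ba, model, model.catalog, a, b)


def evaluate_macro_f1(
    model: TrainedModel,
    pairs: list[GoldStandardPair],
    drugs: list[DrugRecord],
    negatives: list[tuple[str, str]] | None = None,
) -> tuple[float, dict[int, float]]:
    """Macro-averaged F1 of thresholded calls against labelled pairs.

    A type is called for a pair when the maximum score over the two orders
    reaches the threshold (matching the order-invariant label convention).
    Averaged over types with at least one positive label in ``pairs``;
    explicit ``negatives`` contribute all-negative rows.
    """
    negatives = negatives or []
    index = {d.drug_id: d for d in drugs}
    id_pairs = [(p.drug_a_id, p.drug_b_id) for p in pairs] + list(negatives)
    used = sorted({pid for ab in id_pairs for pid in ab})
    missing = [pid for pid in used if pid not in index]
    if missing:
        raise DataError(f"pairs reference unknown drug_id(s): {missing[:10]}")
    feats = predict_features(model, [index[i] for i in used])
    type_ids = model.catalog.type_ids()
    n_types = len(type_ids)
    Y = np.zeros((len(id_pairs), n_types), dtype=bool)
    X_ab = np.stack([np.concatenate([feats[a], feats[b]]) for a, b in id_pairs])
    X_ba = np.stack([np.concatenate([feats[b], feats[a]]) for a, b in id_pairs])
    S = np.maximum(nn.predict_proba(model.params, X_ab), nn.predict_proba(model.params, X_ba))
    P = S >= model.threshold
    col = {t: j for j, t in enumerate(type_ids)}
    for i, p in enumerate(pairs):
        for t in p.type_ids:
            Y[i, col[t]] = True
    per_type: dict[int, float] = {}
    for j, tid in enumerate(type_ids):
        if not Y[:, j].any():
            continue
        tp = int((P[:, j] & Y[:, j]).sum())
        fp = int((P[:, j] & ~Y[:, j]).sum())
        fn = int((~P[:, j] & Y[:, j]).sum())
        per_type[tid] = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    macro = float(np.mean(list(per_type.values()))) if per_type else 0.0
    return macro, per_type


# ---------------------------------------------------------------------------
# gold-standard table I/O and model bundle serialization
# ---------------------------------------------------------------------------


def read_gold_standard(path: str | Path) -> list[GoldStandardPair]:
    """CSV with columns (drug_a_id, drug_b_id, type_ids); type_ids ';'-separated."""
    path = Path(path)
    delim = "\t" if path.suffix.lower() == ".tsv" else ","
    pairs: list[GoldStandardPair] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        required = {"drug_a_id", "drug_b_id", "type_ids"}
        if reader.fieldnames is None or not required <= {f.lower() for f in reader.fieldnames}:
            raise ConfigurationError(f"gold-standard table must have columns {sorted(required)}")
        for row in reader:
            row = {k.lower(): v for k, v in row.items()}
            raw = (row["type_ids"] or "").strip()
            tids = frozenset(int(t) for t in raw.split(";") if t.strip())
            pairs.append(GoldStandardPair(row["drug_a_id"].strip(), row["drug_b_id"].strip(), tids))
    return pairs


def write_gold_standard(pairs: list[GoldStandardPair], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["drug_a_id", "drug_b_id", "type_ids"])
        for p in pairs:
            w.writerow([p.drug_a_id, p.drug_b_id, ";".join(str(t) for t in sorted(p.type_ids))])


def save_model(model: TrainedModel, directory: str | Path) -> None:
    """Versioned bundle: model.json + flat weight vector + reducer + reference + catalogue."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "weights.npy", model.params.to_flat())
    manifest = {
        "version": _MODEL_VERSION,
        "layer_sizes": model.layer_sizes,
        "threshold": model.threshold,
        "seed": model.seed,
        "reference_digest": model.reference_digest,
        "catalog_size": model.catalog_size,
        "config": {
            "hidden_layers": list(model.config.hidden_layers),
            "k": model.config.k,
            "radius": model.config.radius,
            "n_bits": model.config.n_bits,
            "learning_rate": model.config.learning_rate,
            "batch_size": model.config.batch_size,
            "max_epochs": model.config.max_epochs,
            "patience": model.config.patience,
            "val_fraction": model.config.val_fraction,
            "threshold": model.config.threshold,
            "pos_weight_cap": model.config.pos_weight_cap,
            "seed": model.config.seed,
        },
    }
    (directory / "model.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    save_reducer(model.reducer, directory)
    save_reference(model.reference, directory)
    write_catalog(model.catalog, directory / "catalog.csv")


def load_model(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    manifest = json.loads((directory / "model.json").read_text())
    cfg = manifest["config"]
    config = TrainConfig(
        hidden_layers=tuple(cfg["hidden_layers"]),
        k=cfg["k"],
        radius=cfg["radius"],
        n_bits=cfg["n_bits"],
        learning_rate=cfg["learning_rate"],
        batch_size=cfg["batch_size"],
        max_epochs=cfg["max_epochs"],
        patience=cfg["patience"],
        val_fraction=cfg["val_fraction"],
        threshold=cfg["threshold"],
        pos_weight_cap=cfg["pos_weight_cap"],
        seed=cfg["seed"],
    )
    params = nn.MLPParams.from_flat(np.load(directory / "weights.npy"), manifest["layer_sizes"])
    reference = load_reference(directory)
    if reference.digest != manifest["reference_digest"]:
        raise ProvenanceError("model bundle reference digest mismatch")
    model = TrainedModel(
        config=config,
        layer_sizes=manifest["layer_sizes"],
        params=params,
        threshold=manifest["threshold"],
        seed=manifest["seed"],
        reference=reference,
        reducer=load_reducer(directory),
        catalog=load_catalog(directory / "catalog.csv"),
    )
    if model.catalog_size != manifest["catalog_size"]:
        raise ProvenanceError("model bundle catalogue size mismatch")
    return model
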