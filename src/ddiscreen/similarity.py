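"""Structural similarity profiles (SSPs) and their PCA reduction.

A drug's raw feature is its vector of Tanimoto similarities to every drug in
a fixed, ordered reference set (by default the training gold standard's drug
universe).  Profiles are then mean-centered and projected onto the top-k
principal components; k defaults to 100 per drug.  The reference set carries a
content digest so a trained model can refuse featurization built against a
different reference.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chem_io import BitFingerprint, DrugRecord, fingerprint
from .errors import ComparabilityError, ConfigurationError

DEFAULT_K = 100
_ORTHO_TOL = 1e-8


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| over set bits.

    Two all-zero fingerprints are defined to have similarity 0 (not NaN).
    """
    if a.n_bits != b.n_bits or a.radius != b.radius:
        raise ComparabilityError(
            f"incomparable fingerprints: (n_bits={a.n_bits}, radius={a.radius}) "
            f"vs (n_bits={b.n_bits}, radius={b.radius})"
        )
    union = int(np.count_nonzero(a.bits | b.bits))
    if union == 0:
        return 0.0
    inter = int(np.count_nonzero(a.bits & b.bits))
    return inter / union


@dataclass(frozen=True)
class ReferenceSet:
    """Ordered reference drugs with their fingerprints and a content digest."""

    drugs: tuple[DrugRecord, ...]
    fingerprints: tuple[BitFingerprint, ...]
    radius: int
    n_bits: int

    def __post_init__(self):
        if len(self.drugs) != len(self.fingerprints):
            raise ConfigurationError("drugs and fingerprints must align")
        if len(self.drugs) < 2:
            raise ConfigurationError("reference set needs >= 2 drugs")

    def __len__(self) -> int:
        return len(self.drugs)

    @property
    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(f"{self.radius}:{self.n_bits}".encode())
        for d in self.drugs:
            h.update(d.drug_id.encode())
            h.update(b"\x00")
            h.update(d.smiles.encode())
            h.update(b"\x01")
        return h.hexdigest()

    @classmethod
    def from_drugs(
        cls, drugs: list[DrugRecord], radius: int = 2, n_bits: int = 2048
    ) -> "ReferenceSet":
        fps = tuple(fingerprint(d, radius=radius, n_bits=n_bits) for d in drugs)
        return cls(drugs=tuple(drugs), fingerprints=fps, radius=radius, n_bits=n_bits)


@dataclass(frozen=True)
class SSPVector:
    """One drug's similarity profile against a reference set."""

    values: np.ndarray
    drug_id: str

    def __post_init__(self):
        self.values.setflags(write=False)

    def __len__(self) -> int:
        return len(self.values)


def build_ssp(drug: DrugRecord, ref: ReferenceSet) -> SSPVector:
    """Tanimoto similarity of ``drug`` to each reference drug, in reference order."""
    fp = fingerprint(drug, radius=ref.radius, n_bits=ref.n_bits)
    values = np.array([tanimoto(fp, rfp) for rfp in ref.fingerprints], dtype=np.float64)
    return SSPVector(values=values, drug_id=drug.drug_id)


def build_ssp_matrix(drugs: list[DrugRecord], ref: ReferenceSet) -> np.ndarray:
    """Stack SSPs for many drugs into an n x |ref| matrix (vectorized).

    Equivalent to row-wise build_ssp; computed with packed bit arithmetic so
    screening hundreds of drugs stays fast.
    """
    ref_bits = np.stack([f.bits for f in ref.fingerprints]).astype(np.int64)
    ref_pop = ref_bits.sum(axis=1)
    out = np.empty((len(drugs), len(ref)), dtype=np.float64)
    for i, d in enumerate(drugs):
        fp = fingerprint(d, radius=ref.radius, n_bits=ref.n_bits)
        bits = fp.bits.astype(np.int64)
        inter = ref_bits @ bits
        union = ref_pop + bits.sum() - inter
        with np.errstate(invalid="ignore"):
            row = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
        out[i] = row
    return out


@dataclass(frozen=True)
class Reducer:
    """PCA projection fitted on an SSP matrix.

    ``components`` has k orthonormal rows; ``explained_variance`` is
    non-increasing.  Component signs follow a fixed convention (the
    largest-magnitude coordinate of each component is positive) so fits are
    bit-stable across runs.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray
    k: int

    def __post_init__(self):
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.k), atol=1e-6):
            raise ConfigurationError("reducer components are not orthonormal")

    @property
    def input_dim(self) -> int:
        return self.mean.shape[0]


def _fix_signs(components: np.ndarray) -> np.ndarray:
    out = components.copy()
    for i in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[i])))
        if out[i, j] < 0:
            out[i] = -out[i]
    return out


def fit_reducer(ssp_matrix: np.ndarray, k: int = DEFAULT_K) -> Reducer:
    """Fit a top-k PCA on rows of ``ssp_matrix`` (n x m).

    Mean-centers, then takes the k variance-maximizing orthonormal directions
    via SVD.  Requires 1 <= k <= min(n-1, m).  Zero-variance input yields a
    valid reducer with all-zero explained variance and a warning.
    """
    X = np.asarray(ssp_matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ConfigurationError("ssp_matrix must be 2-D with n >= 2 rows")
    n, m = X.shape
    if not (1 <= k <= min(n - 1, m)):
        raise ConfigurationError(
            f"k={k} out of range; need 1 <= k <= min(n-1, m) = {min(n - 1, m)}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of centered data: right singular vectors are principal axes.
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    explained = (s**2) / (n - 1)
    components = _fix_signs(vt[:k])
    ev = explained[:k].copy()
    if np.allclose(ev, 0.0):
        warnings.warn("zero-variance SSP matrix: explained variance is all zero")
    return Reducer(mean=mean, components=components, explained_variance=ev, k=k)


def reduce(ssp: SSPVector | np.ndarray, reducer: Reducer) -> np.ndarray:
    """Project a profile (or a stacked matrix of profiles) onto the components."""
    values = ssp.values if isinstance(ssp, SSPVector) else np.asarray(ssp, dtype=np.float64)
    if values.shape[-1] != reducer.input_dim:
        raise ComparabilityError(
            f"profile dimension {values.shape[-1]} != reducer input {reducer.input_dim}"
        )
    return (values - reducer.mean) @ reducer.components.T


# ---------------------------------------------------------------------------
# serialization: one JSON manifest + flat .npy arrays, bit-stable
# ---------------------------------------------------------------------------

_BUNDLE_VERSION = 1


def save_reducer(reducer: Reducer, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "reducer_mean.npy", reducer.mean)
    np.save(directory / "reducer_components.npy", reducer.components)
    np.save(directory / "reducer_variance.npy", reducer.explained_variance)
    manifest = {"version": _BUNDLE_VERSION, "k": reducer.k, "input_dim": reducer.input_dim}
    (directory / "reducer.json").write_text(json.dumps(manifest, sort_keys=True))


def load_reducer(directory: str | Path) -> Reducer:
    directory = Path(directory)
    manifest = json.loads((directory / "reducer.json").read_text())
    return Reducer(
        mean=np.load(directory / "reducer_mean.npy"),
        components=np.load(directory / "reducer_components.npy"),
        explained_variance=np.load(directory / "reducer_variance.npy"),
        k=manifest["k"],
    )


def save_reference(ref: ReferenceSet, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "version": _BUNDLE_VERSION,
        "radius": ref.radius,
        "n_bits": ref.n_bits,
        "digest": ref.digest,
        "drugs": [
            {"drug_id": d.drug_id, "name": d.name, "smiles": d.smiles} for d in ref.drugs
        ],
        "fingerprints": [np.packbits(f.bits).tobytes().hex() for f in ref.fingerprints],
    }
    (directory / "reference.json").write_text(json.dumps(payload, sort_keys=True))


def load_reference(directory: str | Path) -> ReferenceSet:
    payload = json.loads((Path(directory) / "reference.json").read_text())
    n_bits, radius = payload["n_bits"], payload["radius"]
    drugs = tuple(DrugRecord(d["drug_id"], d["name"], d["smiles"]) for d in payload["drugs"])
    fps = tuple(
        BitFingerprint(
            bits=np.unpackbits(np.frombuffer(bytes.fromhex(h), dtype=np.uint8))[:n_bits],
            n_bits=n_bits,
            radius=radius,
        )
        for h in payload["fingerprints"]
    )
    ref = ReferenceSet(drugs=drugs, fingerprints=fps, radius=radius, n_bits=n_bits)
    if ref.digest != payload["digest"]:
        raise ConfigurationError("reference bundle digest mismatch (corrupted bundle)")
    return ref
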