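import numpy as np
import pytest

import ddiscreen as dd
from ddiscreen.synthetic import make_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted-rule gold standard shared across tests (noise-free)."""
    return make_dataset("tiny", seed=3)


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset):
    """Model trained once on the tiny dataset; read-only for all tests."""
    ds = tiny_dataset
    config = dd.TrainConfig(seed=3, max_epochs=60)
    return dd.train(ds.pairs, ds.drugs, config=config, negatives=ds.negatives)


@pytest.fixture()
def toy_drug_csv(tmp_path):
    path = tmp_path / "drugs.csv"
    path.write_text(
        "drug_id,name,smiles,drug_class\n"
        "d1,ethanol,CCO,solvent\n"
        "d2,benzene,c1ccccc1,aromatic\n"
        "d3,acetic acid,CC(=O)O,acid\n"
    )
    return path


def split_pairs(dataset, frac=0.8, seed=11):
    """Seeded train/test split over labelled pairs and explicit negatives."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(dataset.pairs))
    cut = int(frac * len(dataset.pairs))
    tr = [dataset.pairs[i] for i in idx[:cut]]
    te = [dataset.pairs[i] for i in idx[cut:]]
    nidx = rng.permutation(len(dataset.negatives))
    ncut = int(frac * len(dataset.negatives))
    ntr = [dataset.negatives[i] for i in nidx[:ncut]]
    nte = [dataset.negatives[i] for i in nidx[ncut:]]
    return tr, te, ntr, nte
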