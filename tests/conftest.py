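import numpy as np
import pandas as pd
import pytest

import rankcomm as rc


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_counts(rng):
    """Random 30-gene x 12-cell count matrix with no structure."""
    counts = rng.negative_binomial(2, 0.3, size=(30, 12))
    genes = [f"G{i:04d}" for i in range(1, 31)]
    barcodes = [f"C{i:03d}" for i in range(12)]
    return rc.CountMatrix(counts, genes, barcodes)


@pytest.fixture(scope="session")
def planted_dataset():
    """Synthetic dataset with one planted MIF-CD74 circuit and planted
    co-receptors in the receiver type."""
    cfg = rc.SimConfig(
        n_genes=600,
        cell_types=[("Tumor", 120), ("Tcell", 120), ("Myeloid", 120)],
        lr_circuits=[("MIF", "CD74", "Tumor", "Myeloid", 8.0)],
        planted=[("CXCR4", "Myeloid", 4.0), ("CD44", "Myeloid", 4.0)],
        dropout=0.3,
        seed=11,
    )
    cm, ann, truth = rc.simulate_counts(cfg)
    return cfg, cm, ann, truth


@pytest.fixture(scope="session")
def fitted_crosstalker(planted_dataset):
    cfg, cm, ann, _ = planted_dataset
    lr = rc.read_lr_database(rc.demo_lr_path())
    model = rc.CrossTalker(
        lr_pairs=lr, min_genes=100, n_perm=199, random_state=5
    )
    model.fit(cm, ann["cell_type"].to_numpy())
    return model


@pytest.fixture
def lr_demo_pairs():
    return rc.read_lr_database(rc.demo_lr_path())


def make_annotation(barcodes, labels):
    return pd.DataFrame({"barcode": barcodes, "cell_type": labels})
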