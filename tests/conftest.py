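import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import holomix as hx

ORACLE_DIR = Path(__file__).parent / "oracles"


@pytest.fixture(scope="session")
def mixomics_oracle():
    """Reference values computed once with the mixOmics R package (see
    tests/oracles/generate_mixomics_oracle.R)."""
    with open(ORACLE_DIR / "mixomics_oracle.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def oracle_X():
    return pd.read_csv(ORACLE_DIR / "X.csv", index_col=0)


@pytest.fixture(scope="session")
def oracle_Y():
    return pd.read_csv(ORACLE_DIR / "Y.csv", index_col=0)


@pytest.fixture(scope="session")
def oracle_counts():
    return pd.read_csv(ORACLE_DIR / "counts.csv", index_col=0)


def make_dataset(n=6, p=4, seed=0, name="demo", **kw):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n, p)),
                      index=[f"s{i + 1}" for i in range(n)],
                      columns=[f"f{j + 1}" for j in range(p)])
    return hx.OmicsDataset(name=name, values=df, **kw)


@pytest.fixture
def small_dataset():
    return make_dataset()


def two_class_block(seed=0, p=50, n_informative=5, n_per_class=6,
                    loading_strength=3.0, class_separation=4.0):
    """Strong-effect planted single block used across recovery tests."""
    spec = hx.SyntheticSpec(
        classes=2, n_per_class=n_per_class, shared_factors=1, seed=seed,
        class_separation=class_separation,
        blocks=[hx.BlockSpec("b1", p=p, n_informative=n_informative,
                             loading_strength=loading_strength)])
    datasets, metadata, truth = hx.generate_multiomics(spec)
    labels = metadata.labels_for(datasets[0].sample_ids)
    return datasets[0], labels, truth["b1"]


def three_block_planted(seed=0, p=20, n_informative=4):
    """Three blocks sharing one strong latent factor, binary phenotype
    (mirrors a good-vs-bad storability style contrast)."""
    spec = hx.SyntheticSpec(
        classes=2, n_per_class=6, shared_factors=1, seed=seed,
        class_separation=4.0,
        blocks=[hx.BlockSpec(f"b{i}", p=p, n_informative=n_informative,
                             loading_strength=3.0) for i in range(3)])
    datasets, metadata, truth = hx.generate_multiomics(spec)
    labels = metadata.labels_for(datasets[0].sample_ids)
    return {d.name: d for d in datasets}, labels, truth
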