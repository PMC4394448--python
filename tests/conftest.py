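import dataclasses

import numpy as np
import pytest

from protint import dataset as ds
from protint import synthetic
from protint.features import FeatureSpace, build_space
from protint.seqdata import ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_dataset(X, y, accessions=None, space=None) -> ds.LabeledDataset:
    """LabeledDataset straight from a matrix, for model-level unit tests."""
    X = np.asarray(X, dtype=float)
    if accessions is None:
        accessions = [f"S{i:04d}" for i in range(len(X))]
    if space is None:
        space = FeatureSpace(domain_registry=())
    return ds.LabeledDataset(X=X, y=np.asarray(y, dtype=int),
                             accessions=accessions, space=space)


def separable_blobs(n_per_class=20, dim=4, gap=6.0, seed=0) -> ds.LabeledDataset:
    """Two well-separated Gaussian blobs; trivially classifiable."""
    rng = np.random.default_rng(seed)
    pos = rng.normal(gap, 1.0, size=(n_per_class, dim))
    neg = rng.normal(0.0, 1.0, size=(n_per_class, dim))
    X = np.vstack([pos, neg])
    y = [1] * n_per_class + [0] * n_per_class
    return make_dataset(X, y)


@pytest.fixture
def toy_separable():
    return separable_blobs()


def small_config(preset_name: str, seed: int, **overrides) -> synthetic.SyntheticConfig:
    """Preset scaled down for fast unit tests (shorter sequences, fewer proteins)."""
    base = synthetic.preset(preset_name, seed=seed)
    defaults = dict(n_positives=20, n_background=80, length_range=(50, 100))
    defaults.update(overrides)
    return dataclasses.replace(base, **defaults)


def build_synthetic_dataset(config: synthetic.SyntheticConfig, sample_seed: int = 0):
    """Generate, sample negatives and assemble; returns (dataset, result)."""
    result = synthetic.generate_proteome(config)
    positives = [result.proteome[a] for a in result.positives]
    negatives = ds.sample_negatives(
        result.proteome, positives, ds.SamplingConfig(seed=sample_seed)
    )
    space = build_space(positives + negatives)
    return ds.assemble(positives, negatives, space, seed=sample_seed), result


@pytest.fixture(scope="session")
def strong_small():
    """Small strong-signal dataset shared across model-level tests."""
    config = synthetic.preset("strong", seed=11)
    config = dataclasses.replace(
        config, n_positives=20, n_background=80, length_range=(50, 100)
    )
    return build_synthetic_dataset(config, sample_seed=11)


def diverse_records(n: int, length: int, seed: int, prefix: str = "R") -> list[ProteinRecord]:
    """Random full-alphabet records; mutually non-homologous at 70% identity."""
    rng = np.random.default_rng(seed)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return [
        ProteinRecord(f"{prefix}{i:03d}", "".join(aa[rng.integers(0, 20, size=length)]))
        for i in range(n)
    ]
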