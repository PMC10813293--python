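import numpy as np
import pandas as pd
import pytest

from funorg.synthetic import SimParams, generate_study
from funorg.tables import CompositionTable


def make_composition(values, kind="taxonomic", components=None, samples=None):
    """Column-normalize a raw array into a CompositionTable."""
    arr = np.asarray(values, dtype=float)
    arr = arr / arr.sum(axis=0)
    comp = components or [f"c{i}" for i in range(arr.shape[0])]
    samp = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CompositionTable(pd.DataFrame(arr, index=comp, columns=samp), kind=kind)


def tiny_params(**overrides):
    """Small, fast study used throughout the unit tests."""
    base = dict(n_taxa=60, n_functions=160, n_samples_H=8, n_samples_U=10,
                reads_per_sample=30_000, seed=0)
    base.update(overrides)
    return SimParams(**base)


@pytest.fixture(scope="session")
def tiny_study():
    return generate_study(tiny_params())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
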