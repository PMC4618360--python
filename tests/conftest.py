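import numpy as np
import pytest

from micsel import (
    FeatureMatrix,
    FeatureMap,
    TrialSet,
    design_constant_q_bank,
    extract_features,
    grid_montage,
    laplacian_filter,
    minmax_normalize,
)
from micsel.synthetic import default_benchmark


@pytest.fixture(scope="session")
def bank():
    return design_constant_q_bank()


@pytest.fixture(scope="session")
def benchmark_features(bank):
    """Normalized feature matrix of the default planted benchmark (seed 1),
    after surface Laplacian filtering, plus its ground truth."""
    ts, gt = default_benchmark(seed=1)
    ts = laplacian_filter(ts, grid_montage(4, 5))
    fm = extract_features(ts, bank)
    return fm, minmax_normalize(fm), gt


@pytest.fixture
def random_features():
    """Small random 2-class feature matrix on [0, 1]."""
    rng = np.random.default_rng(42)
    n, p = 40, 12
    values = rng.uniform(size=(n, p))
    labels = np.arange(n) % 2
    return FeatureMatrix(values=values, labels=labels, map=FeatureMap(p, 1))


def make_trialset(data, rate=100.0, labels=None, names=None):
    data = np.asarray(data, dtype=float)
    n_t, n_c = data.shape[0], data.shape[1]
    return TrialSet(
        data=data,
        labels=np.zeros(n_t, dtype=int) if labels is None else labels,
        rate=rate,
        channel_names=names or [f"CH{i}" for i in range(n_c)],
    )
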