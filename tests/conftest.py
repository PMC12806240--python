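import numpy as np
import pytest
import scipy.sparse as sp

from peakcast.data_io import Peak, PeakMatrix
from peakcast.synthetic import SimConfig, simulate_dataset


def make_peaks(p):
    return [Peak("chr1", i * 1000, i * 1000 + 500) for i in range(p)]


def random_peak_matrix(rng, p=50, n=20, density=0.1, with_labels=True, max_count=3):
    counts = sp.random(
        p, n, density=density, random_state=np.random.RandomState(rng.integers(2**31)),
        data_rvs=lambda k: rng.integers(1, max_count + 1, size=k),
    ).tocsr()
    labels = None
    if with_labels:
        labels = [f"T{rng.integers(0, 3)}" for _ in range(n)]
    return PeakMatrix(
        counts=counts,
        peaks=make_peaks(p),
        cell_ids=[f"c{j}" for j in range(n)],
        labels=labels,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def easy_dataset():
    """Small, well-separated 3-type dataset: fast to fit, trivially learnable."""
    cfg = SimConfig(
        n_types=3,
        cells_per_type=(40, 40, 40),
        n_peaks=400,
        peaks_per_type=50,
        background_rate=0.01,
        foreground_rate=0.5,
        shared_fraction=0.0,
        seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def fast_params():
    """Annotator settings scaled down for unit tests."""
    return dict(
        n_draws=50, n_replicates=50, n_components=20,
        n_pairs=600, pairs_per_step=32, random_state=11,
    )
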