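import warnings

import numpy as np
import pytest

from spikeseq.alignment import SimilarityStore


@pytest.fixture(autouse=True)
def _quiet_sklearn():
    # sklearn OPTICS warns about xi extraction on tiny inputs; irrelevant here
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def two_clouds_with_noise(seed: int, separation: float = 3.0, n_cloud: int = 60,
                          n_noise: int = 80, variance: float = 1.3):
    """Two planted Gaussian clouds plus sparse uniform background in 2-D.

    Returns (points, true_labels) with noise labelled -1.  The geometry is a
    distance-matrix analog of the clustering benchmark: dense clouds whose
    overlap defeats density clustering alone, background that defeats
    community detection alone.
    """
    rng = np.random.default_rng(seed)
    sd = np.sqrt(variance)
    a = rng.normal([0.0, 0.0], sd, size=(n_cloud, 2))
    b = rng.normal([separation, 0.0], sd, size=(n_cloud, 2))
    noise = rng.uniform([-8.0, -8.0], [separation + 8.0, 8.0], size=(n_noise, 2))
    pts = np.vstack([a, b, noise])
    labels = np.r_[np.zeros(n_cloud), np.ones(n_cloud), -np.ones(n_noise)].astype(int)
    return pts, labels


def kernel_similarity_store(points: np.ndarray, sigma_frac: float = 0.3) -> SimilarityStore:
    """Gaussian-kernel similarity store over a 2-D point set."""
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(points))
    sigma = sigma_frac * np.median(D)
    E = np.exp(-((D / sigma) ** 2))
    store = SimilarityStore(len(points))
    n = len(points)
    for i in range(n):
        for j in range(i + 1, n):
            store.set(i, j, E[i, j])
    return store
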