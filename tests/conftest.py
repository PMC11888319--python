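"""Shared fixtures: small synthetic datasets with known structure."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


def make_blobs_frame(seed: int, n_clusters: int = 3, separation: float = 10.0,
                     dim: int = 20, n_per: int = 30) -> pd.DataFrame:
    """Gaussian blobs (unit SD) with random centers rescaled so the minimum
    pairwise center separation equals ``separation`` SDs."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, 1.0, (n_clusters, dim))
    dmin = min(
        np.linalg.norm(centers[i] - centers[j])
        for i in range(n_clusters) for j in range(i + 1, n_clusters)
    )
    centers *= separation / dmin
    X = np.vstack([c + rng.normal(0.0, 1.0, (n_per, dim)) for c in centers])
    return pd.DataFrame(X)


@pytest.fixture
def blobs3():
    return make_blobs_frame(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
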