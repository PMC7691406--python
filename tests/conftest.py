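import numpy as np
import pandas as pd
import pytest

from fcclust import GroupLabels


def make_blobs(rng, centers, n_per, sd):
    """Gaussian blobs and their true block labels (1..K)."""
    pts, labs = [], []
    for k, c in enumerate(centers, start=1):
        pts.append(rng.normal(loc=c, scale=sd, size=(n_per, len(c))))
        labs.extend([k] * n_per)
    return np.vstack(pts), np.array(labs)


def make_labels(groups_and_sizes, rng=None):
    """GroupLabels with unit-scale covariates for constructed tests."""
    rng = rng or np.random.default_rng(0)
    labels, rows = [], []
    for g, size in groups_and_sizes:
        labels.extend([g] * size)
        for _ in range(size):
            rows.append((rng.normal(72, 6), int(rng.random() < 0.5), abs(rng.normal())))
    n = len(labels)
    cov = pd.DataFrame(rows, columns=["age", "gender", "motion"],
                       index=[f"sub{i:04d}" for i in range(n)])
    return GroupLabels(labels=labels, covariates=cov)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
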