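import numpy as np
import pandas as pd
import pytest

import leafgmm as lg


@pytest.fixture(scope="session")
def default_dataset():
    return lg.generate_dataset(seed=7)


@pytest.fixture(scope="session")
def aligned(default_dataset):
    return lg.gpa(default_dataset)


@pytest.fixture(scope="session")
def classifier_frame(default_dataset):
    cls = default_dataset.classifiers
    return pd.DataFrame(
        {
            "population": [c.population for c in cls],
            "tree": [c.tree for c in cls],
            "leaf": [c.leaf for c in cls],
            "replica": [c.replica for c in cls],
        }
    )


@pytest.fixture(scope="session")
def tree_averaged(aligned, classifier_frame):
    return lg.average_by_tree(aligned, classifier_frame)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_triangles(rng, n):
    """Well-conditioned random triangles (no near-degenerate ones)."""
    out = []
    while len(out) < n:
        t = rng.uniform(-1, 1, size=(3, 2))
        centered = t - t.mean(axis=0)
        if np.sqrt((centered**2).sum()) > 0.5:
            out.append(t)
    return np.array(out)
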