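from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ndikit.connectome_io import Connectome, default_labels


def make_connectome(weights) -> Connectome:
    """Connectome from a raw matrix with placeholder labels."""
    w = np.asarray(weights, dtype=float)
    return Connectome(
        w, np.array([f"n{i}" for i in range(len(w))], dtype=object), default_labels(len(w))
    )


def random_connected_weighted(n: int, rng: np.random.Generator, p: float = 0.6) -> np.ndarray:
    """Random connected weighted graph (spanning tree plus extra edges)."""
    w = np.zeros((n, n))
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):  # spanning tree keeps it connected
        w[a, b] = w[b, a] = rng.uniform(0.1, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] == 0 and rng.random() < p:
                w[i, j] = w[j, i] = rng.uniform(0.1, 1.0)
    return w


@pytest.fixture
def path3() -> Connectome:
    return make_connectome([[0, 1, 0], [1, 0, 1], [0, 1, 0]])


@pytest.fixture
def triangle() -> Connectome:
    return make_connectome([[0, 1, 1], [1, 0, 1], [1, 1, 0]])


@pytest.fixture
def star4() -> Connectome:
    w = np.zeros((4, 4))
    w[0, 1:] = w[1:, 0] = 1.0
    return make_connectome(w)


def labelled_connectome(weights, groups) -> Connectome:
    w = np.asarray(weights, dtype=float)
    labels = default_labels(len(w))
    labels = pd.DataFrame(labels)
    labels["anatomical_group"] = list(groups)
    return Connectome(w, labels["node_id"].to_numpy(object), labels)
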