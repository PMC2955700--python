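"""Shared fixtures and random-instance builders."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from fragnet.forces import ComponentPlacement


def random_dissimilarity(ids, rng, low=0.5, high=3.0):
    """A random symmetric zero-diagonal dissimilarity DataFrame."""
    n = len(ids)
    vals = rng.uniform(low, high, size=(n, n))
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 0.0)
    return pd.DataFrame(vals, index=ids, columns=ids)


def random_rigid_instance(rng, n_components=None, max_size=5):
    """Random rigid-body instance: centered layouts, placement, D.

    Returns (layouts, placement, D).  Component local layouts are centered;
    positions, centers and angles are generic (no coincident points).
    """
    p = n_components or rng.integers(2, 6)
    layouts = []
    ids = []
    for k in range(p):
        size = int(rng.integers(1, max_size + 1))
        names = [f"c{k}v{i}" for i in range(size)]
        pts = rng.normal(0.0, 1.0, size=(size, 2))
        pts -= pts.mean(axis=0)
        layouts.append({v: pts[i] for i, v in enumerate(names)})
        ids.extend(names)
    placement = ComponentPlacement(
        centers=rng.uniform(-4.0, 4.0, size=(p, 2)),
        angles=rng.uniform(0.0, 2 * np.pi, size=p),
        scale=1.0,
    )
    D = random_dissimilarity(ids, rng)
    return layouts, placement, D


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def two_triangles():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                      ("x", "y"), ("y", "z"), ("x", "z")])
    return g


@pytest.fixture
def small_planar_D(rng):
    """Euclidean distances of a small random point cloud, as a DataFrame."""
    from scipy.spatial.distance import pdist, squareform

    ids = [f"v{i}" for i in range(12)]
    pts = rng.uniform(0.0, 4.0, size=(12, 2))
    return pd.DataFrame(squareform(pdist(pts)), index=ids, columns=ids)
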