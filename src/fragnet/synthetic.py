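"""Synthetic fragmented networks with known ground truth.

Real use cases pair a fragmented network (e.g. gene groups linked by strong
pairwise similarity) with a dissimilarity matrix from an independent source.
These generators emulate that structure with planted groups: tight
within-group distances, larger between-group distances, and a similarity
threshold that fragments the network into many small components.  Because the
ground truth (group labels, exact geometry) is known, recovery can be tested
directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .graph import threshold_network

__all__ = ["PlantedInstance", "planar_instance", "block_dissimilarity"]


@dataclass
class PlantedInstance:
    """A generated network + dissimilarity matrix with planted group structure."""

    network: nx.Graph
    D: pd.DataFrame
    true_groups: dict[str, int]
    generator_params: dict = field(default_factory=dict)


def _similarity_from_distance(D: pd.DataFrame) -> pd.DataFrame:
    """Monotone map d -> 1/(1+d), so distance thresholds translate directly."""
    sim = 1.0 / (1.0 + D.to_numpy(dtype=float))
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=D.index, columns=D.columns)


def planar_instance(
    n_points: int = 60,
    n_groups: int = 12,
    within_spread: float = 0.4,
    between_spread: float = 3.0,
    seed: int | None = None,
) -> PlantedInstance:
    """Gaussian groups in the plane; D is their exact Euclidean distance matrix.

    Group centers sit on a jittered grid with spacing ``between_spread`` and
    points scatter isotropically with standard deviation ``within_spread``,
    so D is perfectly realizable in 2-D (MDS can reach zero stress).  The
    network connects points whose similarity 1/(1+d) exceeds a threshold set
    at the midpoint between the largest within-group and the smallest
    between-group distance (falling back to the 20th percentile of all
    distances when groups overlap), which fragments each group into one or
    more pure components.
    """
    if not n_points >= n_groups >= 1:
        raise ValueError("need n_points >= n_groups >= 1")
    rng = np.random.default_rng(seed)
    # group centers on a jittered grid: nearest centers sit ~between_spread
    # apart whatever n_groups is, and center distances span a broad range
    side = int(np.ceil(np.sqrt(n_groups)))
    cells = np.stack(np.meshgrid(np.arange(side), np.arange(side)), axis=-1).reshape(-1, 2)
    cells = cells[rng.permutation(len(cells))[:n_groups]]
    centers = between_spread * (
        cells + rng.uniform(-0.25, 0.25, size=(n_groups, 2))
    )
    groups = np.sort(rng.integers(0, n_groups, size=n_points))
    # guarantee every group is non-empty
    groups[:n_groups] = np.arange(n_groups)
    points = centers[groups] + rng.normal(0.0, within_spread, size=(n_points, 2))
    ids = [f"v{i:03d}" for i in range(n_points)]
    dvals = squareform(pdist(points))
    off = dvals[~np.eye(n_points, dtype=bool)]
    if off.size and off.max() - off.min() <= 0:
        raise ValueError("degenerate similarity")
    D = pd.DataFrame(dvals, index=ids, columns=ids)
    same = groups[:, None] == groups[None, :]
    iu, ju = np.triu_indices(n_points, k=1)
    within = dvals[iu, ju][same[iu, ju]]
    between = dvals[iu, ju][~same[iu, ju]]
    if len(within) and len(between) and within.max() < between.min():
        d_thr = (within.max() + between.min()) / 2.0
    else:
        d_thr = float(np.percentile(dvals[iu, ju], 20))
    sim = _similarity_from_distance(D)
    network = threshold_network(sim, 1.0 / (1.0 + d_thr), keep_isolated=True)
    return PlantedInstance(
        network=network,
        D=D,
        true_groups={ids[i]: int(groups[i]) for i in range(n_points)},
        generator_params={
            "generator": "planar_instance",
            "n_points": n_points,
            "n_groups": n_groups,
            "within_spread": within_spread,
            "between_spread": between_spread,
            "seed": seed,
            "distance_threshold": float(d_thr),
        },
    )


def block_dissimilarity(
    sizes: list[int],
    d_within: float = 1.0,
    d_between: float = 4.0,
    jitter: float = 0.0,
    seed: int | None = None,
) -> PlantedInstance:
    """Block-structured (ultrametric-like) dissimilarities.

    Entries are ``d_within`` inside a block and ``d_between`` across blocks,
    plus symmetric uniform jitter; the jitter bound keeps the two regimes
    separated.  The network is built by thresholding midway between the two
    levels, so every block becomes exactly one clique component.
    ``d_between`` may optionally vary per block pair via a square array.
    """
    n_blocks = len(sizes)
    cross = np.asarray(d_between, dtype=float)
    if cross.ndim == 0:
        cross = np.full((n_blocks, n_blocks), float(cross))
    elif cross.shape != (n_blocks, n_blocks) or not np.allclose(cross, cross.T):
        raise ValueError("d_between must be a scalar or a symmetric blocks x blocks array")
    bu, bv = np.triu_indices(n_blocks, k=1)
    min_between = float(cross[bu, bv].min()) if len(bu) else float("inf")
    if not min_between > d_within >= 0:
        raise ValueError("need d_between > d_within >= 0")
    if np.isfinite(min_between) and not jitter < (min_between - d_within) / 2.0:
        raise ValueError("jitter must be < (d_between - d_within)/2")
    rng = np.random.default_rng(seed)
    n = int(np.sum(sizes))
    block_of = np.concatenate([np.full(s, b) for b, s in enumerate(sizes)])
    ids = [f"v{i:03d}" for i in range(n)]
    base = np.where(
        block_of[:, None] == block_of[None, :],
        d_within,
        cross[block_of[:, None], block_of[None, :]],
    )
    noise = rng.uniform(-jitter, jitter, size=(n, n))
    noise = (noise + noise.T) / 2.0
    dvals = np.clip(base + noise, 0.0, None)
    np.fill_diagonal(dvals, 0.0)
    D = pd.DataFrame(dvals, index=ids, columns=ids)
    sim = _similarity_from_distance(D)
    d_thr = (d_within + min_between) / 2.0
    network = threshold_network(sim, 1.0 / (1.0 + d_thr), keep_isolated=True)
    return PlantedInstance(
        network=network,
        D=D,
        true_groups={ids[i]: int(block_of[i]) for i in range(n)},
        generator_params={
            "generator": "block_dissimilarity",
            "sizes": list(map(int, sizes)),
            "d_within": d_within,
            "d_between": d_between,
            "jitter": jitter,
            "seed": seed,
            "distance_threshold": d_thr,
        },
    )
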