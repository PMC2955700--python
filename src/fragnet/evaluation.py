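"""Quantitative layout evaluation.

The central quality measure is the Pearson correlation between the entries of
the vertex dissimilarity matrix and the Euclidean distances between the same
vertex pairs in the 2-D layout, over *all* pairs (within and across
components).  A random scatter scores near zero; a perfect planar realization
scores one.  A threshold sweep traces how this correlation responds to
network fragmentation for several layout methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .graph import (
    align_matrix,
    dissimilarity_from_similarity,
    find_components,
    local_clustering_coefficient,
    threshold_network,
    validate_dissimilarity,
)

__all__ = [
    "EvaluationReport",
    "layout_correlation",
    "fragmentation_sweep",
    "nearest_component_links",
]


@dataclass
class EvaluationReport:
    """Layout-distance agreement for one layout.

    ``pearson_r`` is NaN with ``r_defined=False`` when either distance vector
    is constant (correlation undefined); ``stress`` is the raw stress over
    all vertex pairs.
    """

    pearson_r: float
    stress: float
    n_pairs: int
    method_name: str = ""
    seed: int | None = None
    r_defined: bool = True


def layout_correlation(
    layout: dict[str, np.ndarray],
    D: pd.DataFrame,
    method_name: str = "",
    seed: int | None = None,
) -> EvaluationReport:
    """Pearson correlation between dissimilarities and layout distances."""
    validate_dissimilarity(D)
    ids = list(layout)
    dmat = align_matrix(D, ids).to_numpy(dtype=float)
    coords = np.asarray([layout[v] for v in ids], dtype=float)
    layout_d = pdist(coords)
    iu, ju = np.triu_indices(len(ids), k=1)
    target_d = dmat[iu, ju]
    n_pairs = len(target_d)
    stress = float(np.sum((target_d - layout_d) ** 2))
    if np.ptp(target_d) == 0 or np.ptp(layout_d) == 0:
        return EvaluationReport(float("nan"), stress, n_pairs, method_name, seed, False)
    r = float(pearsonr(target_d, layout_d).statistic)
    return EvaluationReport(r, stress, n_pairs, method_name, seed, True)


def fragmentation_sweep(
    similarity: pd.DataFrame,
    thresholds: list[float],
    methods: dict[str, object],
    reps: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlation of several layout methods across a threshold sweep.

    For each threshold the network is rebuilt (isolated vertices kept, so the
    vertex set is fixed) and every method — a callable
    ``method(graph, D, seed) -> layout dict`` — is run ``reps`` times with
    derived seeds shared across methods.  Returns a tidy frame with one row
    per (threshold, method): mean and std of the correlation plus the
    component count and average local clustering coefficient of the network.
    """
    from ._seeding import derived_seed

    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    D = dissimilarity_from_similarity(similarity, mode="one_minus")
    rows = []
    for t_idx, thr in enumerate(thresholds):
        graph = threshold_network(similarity, thr, keep_isolated=True)
        n_components = len(find_components(graph))
        _, avg_cc = local_clustering_coefficient(graph)
        for name, method in methods.items():
            rs = []
            for rep in range(reps):
                rep_seed = derived_seed(seed, t_idx, rep)
                coords = method(graph, D, rep_seed)
                report = layout_correlation(coords, D, method_name=name, seed=rep_seed)
                rs.append(report.pearson_r)
            rows.append(
                {
                    "threshold": thr,
                    "method": name,
                    "mean_r": float(np.nanmean(rs)),
                    "std_r": float(np.nanstd(rs)),
                    "n_components": n_components,
                    "avg_clustering": avg_cc,
                    "reps": reps,
                }
            )
    return pd.DataFrame(rows)


def nearest_component_links(
    delta: np.ndarray, k_links: int = 2
) -> list[tuple[int, int, float]]:
    """For each component, its ``k_links`` most similar (smallest-delta)
    partners; duplicate undirected links merged.

    The returned weight is ``(delta_max - delta_kl) / delta_max`` — 1 for the
    globally most similar possible pair, 0 for the most distant — suitable as
    a relative line width.  Ties break toward the lower component index.
    """
    delta = np.asarray(delta, dtype=float)
    p = len(delta)
    if p < 2:
        raise ValueError("at least two components required")
    k_links = min(k_links, p - 1)
    iu, ju = np.triu_indices(p, k=1)
    delta_max = float(delta[iu, ju].max())
    pairs: set[tuple[int, int]] = set()
    for k in range(p):
        order = sorted((delta[k, l], l) for l in range(p) if l != k)
        for _, l in order[:k_links]:
            pairs.add((min(k, l), max(k, l)))
    links = []
    for k, l in sorted(pairs):
        weight = (delta_max - delta[k, l]) / delta_max if delta_max > 0 else 1.0
        links.append((k, l, float(weight)))
    return links
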