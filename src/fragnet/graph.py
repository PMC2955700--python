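"""Graph handling: components, threshold construction, clustering statistics.

Networks are plain undirected :class:`networkx.Graph` objects over string
vertex ids (no self-loops, no parallel edges).  An optional binary display
class (e.g. over-expressed in one of two phenotypes) lives in the node
attribute ``"class"``; it plays no role in any computation.

Labeled square matrices (similarities and dissimilarities) are
:class:`pandas.DataFrame` objects whose index and columns are the vertex ids.
All matrix access in the package is label-checked, never positional.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "find_components",
    "threshold_network",
    "local_clustering_coefficient",
    "dissimilarity_from_similarity",
    "validate_square_matrix",
    "validate_dissimilarity",
    "align_matrix",
]


def validate_square_matrix(matrix: pd.DataFrame, *, atol: float = 1e-9) -> pd.DataFrame:
    """Check that ``matrix`` is a labeled, square, symmetric, finite DataFrame.

    Raises ``ValueError`` naming the worst offending pair on asymmetry.
    """
    if not isinstance(matrix, pd.DataFrame):
        raise TypeError("expected a labeled pandas DataFrame")
    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"matrix is not square: shape {matrix.shape}")
    if list(matrix.index) != list(matrix.columns):
        raise ValueError("matrix row labels do not match column labels")
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix contains non-finite entries")
    asym = np.abs(values - values.T)
    worst = np.unravel_index(np.argmax(asym), asym.shape)
    if asym[worst] > atol:
        i, j = worst
        raise ValueError(
            "matrix is not symmetric: worst pair "
            f"({matrix.index[i]!r}, {matrix.columns[j]!r}) differs by {asym[worst]:.3g}"
        )
    return matrix


def validate_dissimilarity(matrix: pd.DataFrame, *, atol: float = 1e-12) -> pd.DataFrame:
    """Validate a dissimilarity matrix: symmetric, zero diagonal, nonnegative."""
    validate_square_matrix(matrix, atol=atol)
    values = matrix.to_numpy(dtype=float)
    if np.any(np.abs(np.diag(values)) > atol):
        raise ValueError("dissimilarity matrix has a nonzero diagonal")
    if np.any(values < -atol):
        raise ValueError("dissimilarity matrix has negative entries")
    return matrix


def align_matrix(matrix: pd.DataFrame, vertex_ids: Iterable[str]) -> pd.DataFrame:
    """Reindex ``matrix`` to ``vertex_ids``, erroring on missing labels."""
    ids = list(vertex_ids)
    missing = [v for v in ids if v not in matrix.index]
    if missing:
        raise ValueError(f"matrix is missing vertex ids: {missing[:5]}")
    return matrix.loc[ids, ids]


def find_components(network: nx.Graph) -> list[list[str]]:
    """Connected components as an ordered partition of the vertex set.

    Blocks are sorted by their smallest member id and each block lists its
    members in sorted order, making the partition deterministic regardless of
    node insertion order.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty graph")
    blocks = [sorted(block) for block in nx.connected_components(network)]
    blocks.sort(key=lambda b: b[0])
    return blocks


def threshold_network(
    similarity: pd.DataFrame, threshold: float, *, keep_isolated: bool = True
) -> nx.Graph:
    """Build a network with an edge wherever similarity strictly exceeds ``threshold``.

    ``keep_isolated=False`` drops vertices of degree zero (only vertices
    connected to at least one other vertex remain).
    """
    validate_square_matrix(similarity)
    ids = [str(v) for v in similarity.index]
    values = similarity.to_numpy(dtype=float)
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    iu, ju = np.triu_indices(len(ids), k=1)
    above = values[iu, ju] > threshold
    graph.add_edges_from((ids[i], ids[j]) for i, j in zip(iu[above], ju[above]))
    if not keep_isolated:
        graph.remove_nodes_from([v for v, deg in graph.degree() if deg == 0])
    return graph


def local_clustering_coefficient(network: nx.Graph) -> tuple[dict[str, float], float]:
    """Per-vertex local clustering coefficients and their average.

    The coefficient of a vertex is the fraction of its neighbor pairs that are
    themselves adjacent.  The average is taken over vertices of degree >= 2
    only (the Watts-Strogatz convention; degree < 2 leaves the coefficient
    undefined), so a complete graph averages exactly 1.  Returns NaN as the
    average when no vertex has degree >= 2.
    """
    coeffs = nx.clustering(network)
    eligible = [c for v, c in coeffs.items() if network.degree(v) >= 2]
    average = float(np.mean(eligible)) if eligible else float("nan")
    return dict(coeffs), average


def dissimilarity_from_similarity(
    similarity: pd.DataFrame, mode: str = "one_minus"
) -> pd.DataFrame:
    """Convert a similarity matrix to a dissimilarity matrix.

    mode ``"one_minus"``: min-max rescale the off-diagonal similarities to
    [0, 1] and return ``1 - s``, diagonal forced to zero.  mode
    ``"identity"``: the input already holds dissimilarities; validate and pass
    through unchanged.
    """
    if mode == "identity":
        return validate_dissimilarity(similarity)
    if mode != "one_minus":
        raise ValueError(f"unknown mode {mode!r}")
    validate_square_matrix(similarity)
    values = similarity.to_numpy(dtype=float).copy()
    n = values.shape[0]
    off = ~np.eye(n, dtype=bool)
    smin, smax = values[off].min(), values[off].max()
    if smax - smin <= 0:
        raise ValueError("degenerate similarity")
    scaled = (values - smin) / (smax - smin)
    dissim = 1.0 - scaled
    dissim = (dissim + dissim.T) / 2.0
    np.clip(dissim, 0.0, None, out=dissim)
    np.fill_diagonal(dissim, 0.0)
    return pd.DataFrame(dissim, index=similarity.index, columns=similarity.columns)
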