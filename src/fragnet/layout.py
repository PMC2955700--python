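"""Per-component internal layout (stage one of the pipeline).

Each connected component gets its own coordinate system, laid out with the
Fruchterman-Reingold force-directed algorithm and then mean-centered so the
component can later be treated as a rigid body rotating about its centroid.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

__all__ = ["fr_layout", "center", "layout_array", "rescale_to_distances"]

DEFAULT_FR_ITERATIONS = 500


def center(layout: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Translate a layout so its mean coordinate is the origin.

    Idempotent and distance-preserving; a single point maps to the origin.
    """
    if not layout:
        return {}
    ids = list(layout)
    coords = np.asarray([layout[v] for v in ids], dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("layout contains non-finite coordinates")
    coords = coords - coords.mean(axis=0)
    return {v: coords[i] for i, v in enumerate(ids)}


def fr_layout(
    component: nx.Graph,
    iterations: int = DEFAULT_FR_ITERATIONS,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Fruchterman-Reingold layout of one connected component, mean-centered.

    Initial positions are drawn from the seeded generator, so the result is
    deterministic for a fixed seed.  The ideal edge length is sqrt(area/n)
    with unit area, and the temperature decays linearly over the iteration
    budget (the classical 1991 schedule, as implemented by networkx).
    """
    if component.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if component.number_of_nodes() > 1 and not nx.is_connected(component):
        raise ValueError("component must be connected")
    if component.number_of_nodes() == 1:
        (v,) = component.nodes
        return {v: np.zeros(2)}
    pos = nx.spring_layout(component, iterations=iterations, seed=seed, weight=None)
    return center({v: np.asarray(p, dtype=float) for v, p in pos.items()})


def layout_array(layout: dict[str, np.ndarray], ids: list[str]) -> np.ndarray:
    """Stack a layout dict into an (n, 2) array following ``ids`` order."""
    return np.asarray([layout[v] for v in ids], dtype=float)


def rescale_to_distances(
    layouts: list[dict[str, np.ndarray]], D
) -> list[dict[str, np.ndarray]]:
    """Express each component's internal layout in the units of D.

    Force-directed coordinates carry an arbitrary unit; the springs that
    couple components to each other are expressed in the unit of the
    dissimilarity matrix.  For the two coordinate systems to be commensurate
    each component is uniformly scaled so that its mean internal pairwise
    layout distance equals its mean internal pairwise dissimilarity.
    Singletons, and components whose internal dissimilarities are all zero,
    are left untouched.  Shapes (angles, distance ratios) are preserved.
    """
    from .graph import align_matrix

    out = []
    for layout in layouts:
        ids = list(layout)
        if len(ids) < 2:
            out.append(layout)
            continue
        pts = np.asarray([layout[v] for v in ids], dtype=float)
        iu, ju = np.triu_indices(len(ids), k=1)
        mean_layout = float(np.linalg.norm(pts[iu] - pts[ju], axis=-1).mean())
        dmat = align_matrix(D, ids).to_numpy(dtype=float)
        mean_target = float(dmat[iu, ju].mean())
        if mean_layout <= 0 or mean_target <= 0:
            out.append(layout)
            continue
        factor = mean_target / mean_layout
        out.append({v: pts[i] * factor for i, v in enumerate(ids)})
    return out
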