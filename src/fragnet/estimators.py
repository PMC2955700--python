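"""Estimator interface to the two layout pipelines.

Both estimators are transform-shaped in the scikit-learn sense: ``fit`` takes
a precomputed vertex dissimilarity matrix (a labeled DataFrame) plus the
network, and exposes the 2-D embedding and per-stage diagnostics as fitted
attributes.  ``FragVizEmbedding`` is the fast approximation (component MDS +
annealed rotation); ``ExactFragVizEmbedding`` runs the full rigid-body spring
simulation.  Module-level functions (`fragviz_layout`, `exact_layout`, the
method registry used by sweeps) are thin wrappers over the estimators.
"""

from __future__ import annotations

import time
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._seeding import ANNEAL_STAGE, FR_STAGE, INIT_STAGE, MDS_STAGE, derived_seed
from .approx import (
    AnnealingSchedule,
    classical_mds_init,
    component_distances,
    optimize_rotations,
    scaling_factor,
    smacof_mds,
)
from .evaluation import layout_correlation
from .forces import (
    ComponentPlacement,
    SimulationParams,
    assemble_positions,
    simulate_exact,
)
from .graph import (
    align_matrix,
    dissimilarity_from_similarity,
    find_components,
    threshold_network,
    validate_dissimilarity,
)
from .layout import DEFAULT_FR_ITERATIONS, center, fr_layout, rescale_to_distances

__all__ = [
    "FragVizEmbedding",
    "ExactFragVizEmbedding",
    "fragviz_layout",
    "exact_layout",
    "fr_whole_layout",
    "mds_layout",
    "LAYOUT_METHODS",
    "params_from_config",
]


def _resolve_seed(random_state) -> int:
    if random_state is None:
        return int(np.random.SeedSequence().generate_state(1)[0] & 0x7FFFFFFF)
    if isinstance(random_state, (int, np.integer)):
        return int(random_state)
    raise TypeError("random_state must be an int or None")


def _resolve_inputs(X, graph, threshold):
    """Turn (X, graph, threshold) into a validated (graph, D) pair.

    X is either a dissimilarity DataFrame accompanying an explicit graph, or
    — when ``threshold`` is set and no graph is given — a similarity matrix
    from which both the network and the dissimilarities are derived.
    """
    if not isinstance(X, pd.DataFrame):
        raise TypeError(
            "X must be a labeled square DataFrame (vertex ids as index/columns)"
        )
    if graph is None:
        if threshold is None:
            raise ValueError("either a graph or a similarity threshold is required")
        graph = threshold_network(X, threshold, keep_isolated=True)
        D = dissimilarity_from_similarity(X, mode="one_minus")
    else:
        D = validate_dissimilarity(X)
        missing = [v for v in graph.nodes if v not in D.index]
        if missing:
            raise ValueError(f"dissimilarity matrix is missing vertices: {missing[:5]}")
    return graph, D


def _component_layouts(graph, partition, iterations, seed):
    return [
        fr_layout(graph.subgraph(block), iterations=iterations,
                  seed=derived_seed(seed, FR_STAGE, k))
        for k, block in enumerate(partition)
    ]


def _bounding_circle_overlaps(layouts, placement) -> int:
    """Count component pairs whose bounding circles intersect (diagnostic only)."""
    radii = []
    for layout in layouts:
        pts = np.asarray(list(layout.values()), dtype=float)
        radii.append(float(np.linalg.norm(pts, axis=1).max()) if len(pts) else 0.0)
    centers = placement.scale * placement.centers
    count = 0
    for k in range(len(layouts)):
        for l in range(k + 1, len(layouts)):
            if np.linalg.norm(centers[k] - centers[l]) < radii[k] + radii[l]:
                count += 1
    return count


class FragVizEmbedding(BaseEstimator):
    """Two-stage layout of a fragmented network, fast approximation.

    Stage one lays out each connected component independently with
    Fruchterman-Reingold.  Stage two places the components: average-linkage
    component distances are embedded by SMACOF MDS, a single scale K fits
    component size to center spacing, and each component is rotated in place
    by annealed torque steps so that cross-component vertex distances track
    the prescribed dissimilarities.

    Parameters
    ----------
    fr_iterations : force-directed iterations per component.
    mds_max_iter, mds_tol : SMACOF stopping rules (relative stress change).
    mds_init : "random" (seeded, in the unit disk) or "classical"
        (Torgerson double-centering start).
    anneal_sweeps, anneal_t0, anneal_decay : rotation-phase annealing
        schedule; ``anneal_t0=0`` is greedy.
    step_phi : rotation step constant (shared with the torque rule).
    threshold : when set, ``fit(X)`` treats X as a *similarity* matrix and
        builds the network by strict thresholding instead of requiring
        ``graph=``.
    random_state : int seed; every internal stage derives its own child seed.

    Attributes (after fit)
    ----------
    embedding_ : (n, 2) array in the row order of X.
    coords_ : dict vertex id -> 2-D position.
    components_ : ordered vertex-id blocks.
    placement_ : centers, angles and scale K of the components.
    stress_ : final inter-component spring stress.
    correlation_ : Pearson r between dissimilarities and layout distances.
    diagnostics_ : stage timings, SMACOF/rotation stress traces, overlap count.
    """

    def __init__(
        self,
        *,
        fr_iterations: int = DEFAULT_FR_ITERATIONS,
        mds_max_iter: int = 300,
        mds_tol: float = 1e-9,
        mds_init: str = "random",
        anneal_sweeps: int = 50,
        anneal_t0: float = 1.0,
        anneal_decay: float = 0.9,
        step_phi: float = 0.1,
        threshold: float | None = None,
        random_state: int | None = None,
    ):
        self.fr_iterations = fr_iterations
        self.mds_max_iter = mds_max_iter
        self.mds_tol = mds_tol
        self.mds_init = mds_init
        self.anneal_sweeps = anneal_sweeps
        self.anneal_t0 = anneal_t0
        self.anneal_decay = anneal_decay
        self.step_phi = step_phi
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None, *, graph: nx.Graph | None = None):
        seed = _resolve_seed(self.random_state)
        graph, D = _resolve_inputs(X, graph, self.threshold)
        timings: dict[str, float] = {}

        t0 = time.perf_counter()
        partition = find_components(graph)
        layouts = _component_layouts(graph, partition, self.fr_iterations, seed)
        if len(partition) > 1:
            # express internal coordinates in the units of D so the springs
            # (rest lengths from D) and the component shapes are commensurate;
            # with one component there is no inter-component frame to match
            layouts = rescale_to_distances(layouts, D)
        timings["fr"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        delta = component_distances(D, partition)
        init = classical_mds_init(delta) if self.mds_init == "classical" else None
        centers, mds_trace = smacof_mds(
            delta,
            init=init,
            seed=derived_seed(seed, MDS_STAGE),
            max_iter=self.mds_max_iter,
            tol=self.mds_tol,
        )
        timings["mds"] = time.perf_counter() - t0

        if len(partition) == 1:
            K = 1.0
        else:
            # The size/spacing ratio exists to *avoid overlap*: with internal
            # layouts already in D units, shrinking the center spread below
            # its MDS geometry would discard inter-component structure, so
            # the ratio only ever expands the spacing (K >= 1).
            K = max(1.0, scaling_factor(layouts, centers))

        t0 = time.perf_counter()
        schedule = AnnealingSchedule(
            t0=self.anneal_t0,
            decay=self.anneal_decay,
            sweeps=self.anneal_sweeps,
            seed=derived_seed(seed, ANNEAL_STAGE),
            step_phi=self.step_phi,
        )
        angles, rot_trace = optimize_rotations(
            layouts, centers, K, D, partition, schedule
        )
        timings["rotation"] = time.perf_counter() - t0

        placement = ComponentPlacement(centers=centers, angles=angles, scale=K)
        ids, positions, _ = assemble_positions(layouts, placement)
        coords = {v: positions[i] for i, v in enumerate(ids)}
        report = layout_correlation(coords, D, method_name="fragviz", seed=seed)

        self.graph_ = graph
        self.components_ = partition
        self.layouts_ = layouts
        self.delta_ = delta
        self.placement_ = placement
        self.coords_ = coords
        self.embedding_ = np.asarray([coords[v] for v in D.index if v in coords])
        self.n_features_in_ = X.shape[1]
        self.stress_ = rot_trace[-1]
        self.correlation_ = report.pearson_r
        self.diagnostics_ = {
            "seed": seed,
            "n_components": len(partition),
            "scale_K": K,
            "timings": timings,
            "mds_stress_trace": mds_trace,
            "rotation_stress_trace": rot_trace,
            "overlapping_component_pairs": _bounding_circle_overlaps(layouts, placement),
            "evaluation": report,
        }
        return self

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X, y, **fit_params).embedding_


class ExactFragVizEmbedding(BaseEstimator):
    """Two-stage layout with the exact rigid-body spring simulation.

    Stage one is identical to :class:`FragVizEmbedding`; stage two starts the
    components at a seeded random placement and integrates translation and
    rotation under Hooke forces between all cross-component vertex pairs
    until the residual forces fall below ``force_tolerance``.
    """

    def __init__(
        self,
        *,
        fr_iterations: int = DEFAULT_FR_ITERATIONS,
        step_c: float = 0.1,
        step_phi: float = 0.1,
        max_iterations: int = 2000,
        force_tolerance: float = 1e-4,
        threshold: float | None = None,
        random_state: int | None = None,
    ):
        self.fr_iterations = fr_iterations
        self.step_c = step_c
        self.step_phi = step_phi
        self.max_iterations = max_iterations
        self.force_tolerance = force_tolerance
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None, *, graph: nx.Graph | None = None):
        seed = _resolve_seed(self.random_state)
        graph, D = _resolve_inputs(X, graph, self.threshold)
        partition = find_components(graph)
        layouts = _component_layouts(graph, partition, self.fr_iterations, seed)
        if len(partition) > 1:
            layouts = rescale_to_distances(layouts, D)
        params = SimulationParams(
            step_c=self.step_c,
            step_phi=self.step_phi,
            max_iterations=self.max_iterations,
            force_tolerance=self.force_tolerance,
        )
        placement, log = simulate_exact(
            layouts, D, params, seed=derived_seed(seed, INIT_STAGE)
        )
        ids, positions, _ = assemble_positions(layouts, placement)
        coords = {v: positions[i] for i, v in enumerate(ids)}
        report = layout_correlation(coords, D, method_name="exact", seed=seed)

        self.graph_ = graph
        self.components_ = partition
        self.layouts_ = layouts
        self.placement_ = placement
        self.coords_ = coords
        self.embedding_ = np.asarray([coords[v] for v in D.index if v in coords])
        self.n_features_in_ = X.shape[1]
        self.iteration_log_ = log
        self.stress_ = log[-1][2]
        self.correlation_ = report.pearson_r
        self.diagnostics_ = {
            "seed": seed,
            "n_components": len(partition),
            "n_iterations": len(log),
            "final_max_force": log[-1][1],
            "iteration_log": log,
            "evaluation": report,
        }
        return self

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X, y, **fit_params).embedding_


# ---------------------------------------------------------------------------
# thin functional wrappers and the method registry used by sweeps / the CLI

_CONFIG_KEYS = {
    "fr.iterations": ("fr_iterations", int),
    "mds.max_iter": ("mds_max_iter", int),
    "mds.tol": ("mds_tol", float),
    "mds.init": ("mds_init", str),
    "anneal.sweeps": ("anneal_sweeps", int),
    "anneal.t0": ("anneal_t0", float),
    "anneal.decay": ("anneal_decay", float),
    "step.phi": ("step_phi", float),
    "step.c": ("step_c", float),
    "sim.max_iterations": ("max_iterations", int),
    "sim.force_tolerance": ("force_tolerance", float),
    "seed": ("random_state", int),
}


def params_from_config(config: dict) -> dict:
    """Map dotted config keys (``fr.iterations`` ...) to estimator parameters."""
    params = {}
    for key, value in config.items():
        if key not in _CONFIG_KEYS:
            raise ValueError(f"unknown config key {key!r}")
        name, cast = _CONFIG_KEYS[key]
        params[name] = cast(value)
    return params


def _pick(params: dict, estimator_cls) -> dict:
    valid = estimator_cls().get_params()
    return {k: v for k, v in params.items() if k in valid}


def fragviz_layout(
    network: nx.Graph,
    D: pd.DataFrame,
    config: dict | None = None,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], ComponentPlacement, dict]:
    """Approximate two-stage layout; returns (coords, placement, diagnostics)."""
    params = _pick(params_from_config(config or {}), FragVizEmbedding)
    params.setdefault("random_state", seed)
    est = FragVizEmbedding(**params).fit(D, graph=network)
    return est.coords_, est.placement_, est.diagnostics_


def exact_layout(
    network: nx.Graph,
    D: pd.DataFrame,
    config: dict | None = None,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], ComponentPlacement, dict]:
    """Exact simulation layout; returns (coords, placement, diagnostics)."""
    params = _pick(params_from_config(config or {}), ExactFragVizEmbedding)
    params.setdefault("random_state", seed)
    est = ExactFragVizEmbedding(**params).fit(D, graph=network)
    return est.coords_, est.placement_, est.diagnostics_


def fr_whole_layout(
    graph: nx.Graph,
    seed: int = 0,
    iterations: int = DEFAULT_FR_ITERATIONS,
) -> dict[str, np.ndarray]:
    """Plain Fruchterman-Reingold on the whole graph at once, mean-centered.

    The baseline the two-stage method is compared against: component
    placement is left to chance.  Uses the same derived seed as the first
    component of the two-stage pipeline, so on a connected graph the two
    methods coincide exactly.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if graph.number_of_nodes() == 1:
        (v,) = graph.nodes
        return {v: np.zeros(2)}
    pos = nx.spring_layout(
        graph, iterations=iterations, seed=derived_seed(seed, FR_STAGE, 0), weight=None
    )
    return center({v: np.asarray(p, dtype=float) for v, p in pos.items()})


def mds_layout(
    D: pd.DataFrame,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> dict[str, np.ndarray]:
    """Plain SMACOF MDS of the full vertex dissimilarity matrix.

    Vertices are processed in sorted-id order for reproducibility; this makes
    the result coincide exactly with the two-stage pipeline on an edgeless
    network (where every vertex is its own component).
    """
    ids = sorted(str(v) for v in D.index)
    dmat = align_matrix(validate_dissimilarity(D), ids).to_numpy(dtype=float)
    X, _ = smacof_mds(dmat, seed=derived_seed(seed, MDS_STAGE), max_iter=max_iter, tol=tol)
    return {v: X[i] for i, v in enumerate(ids)}


def _method_fr(graph, D, seed):
    return fr_whole_layout(graph, seed=seed)


def _method_fragviz(graph, D, seed):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fragviz_layout(graph, D, seed=seed)[0]


def _method_exact(graph, D, seed):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return exact_layout(graph, D, seed=seed)[0]


def _method_mds(graph, D, seed):
    return mds_layout(D, seed=seed)


LAYOUT_METHODS = {
    "fr": _method_fr,
    "fragviz": _method_fragviz,
    "exact": _method_exact,
    "mds": _method_mds,
}
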