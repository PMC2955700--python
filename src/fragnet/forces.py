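"""Exact semi-physical simulation of component placement.

Components are rigid bodies (boards); every pair of vertices in *different*
components is joined by a Hooke spring whose rest length is the prescribed
dissimilarity d_ij.  Under infinite friction the system carries no momentum:
at each step every component translates proportionally to the mean force on
its vertices and rotates proportionally to the net torque divided by its
moment of inertia, until all residual forces are negligible.

Springs within a component are omitted: a rigid body's internal pair forces
cancel in both the force sum and the torque, so including them changes
nothing (asserted as a property test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import align_matrix, validate_dissimilarity

__all__ = [
    "ComponentPlacement",
    "SimulationParams",
    "global_position",
    "rotation_matrix",
    "assemble_positions",
    "spring_force",
    "net_forces",
    "component_update",
    "simulate_exact",
    "total_stress",
]

COINCIDENT_EPS = 1e-9


@dataclass
class ComponentPlacement:
    """Rigid placement of p components: centers c_k, angles phi_k, center scale K.

    A vertex with centered local coordinates v in component k sits at
    ``R(phi_k) @ v + K * c_k`` globally.  The exact simulation keeps K = 1;
    the approximate method fits K to balance component size against spacing.
    """

    centers: np.ndarray  # (p, 2)
    angles: np.ndarray  # (p,)
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        self.angles = np.asarray(self.angles, dtype=float).ravel()
        if len(self.centers) != len(self.angles):
            raise ValueError("one center and one angle per component required")
        if not (np.isfinite(self.centers).all() and np.isfinite(self.angles).all()):
            raise ValueError("placement must be finite")
        if not self.scale > 0:
            raise ValueError("scale K must be positive")

    @property
    def n_components(self) -> int:
        return len(self.angles)


@dataclass
class SimulationParams:
    """Step sizes and stopping rules for the exact simulation.

    ``step_c`` and ``step_phi`` are the proportionality constants turning the
    (mass-normalised) linear and angular accelerations into per-step
    displacement and rotation; small values keep the stress descent monotone.
    ``force_tolerance`` is the residual-force threshold (in units of the
    dissimilarities) below which the system counts as converged.
    """

    mass: float = 1.0
    step_c: float = 0.1
    step_phi: float = 0.1
    max_iterations: int = 2000
    force_tolerance: float = 1e-4

    def __post_init__(self) -> None:
        if min(self.mass, self.step_c, self.step_phi, self.force_tolerance) <= 0:
            raise ValueError("all simulation parameters must be positive")


def rotation_matrix(phi: float) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, -s], [s, c]])


def global_position(v: np.ndarray, phi: float, c: np.ndarray, K: float = 1.0) -> np.ndarray:
    """Global position g = R(phi) @ v + K*c of a local point v in a placed component."""
    return rotation_matrix(phi) @ np.asarray(v, dtype=float) + K * np.asarray(c, dtype=float)


def assemble_positions(
    layouts: list[dict[str, np.ndarray]], placement: ComponentPlacement
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Flatten per-component layouts into global coordinates.

    Returns (vertex ids, (n,2) global positions, (n,) component index).
    Rotation and center shift are skipped bit-exactly when they are the
    identity, so a trivial placement returns the local coordinates unchanged.
    """
    ids: list[str] = []
    rows: list[np.ndarray] = []
    comp_idx: list[int] = []
    for k, layout in enumerate(layouts):
        local = np.asarray([layout[v] for v in layout], dtype=float)
        phi = placement.angles[k]
        if phi != 0.0:
            local = local @ rotation_matrix(phi).T
        offset = placement.scale * placement.centers[k]
        if np.any(offset != 0.0):
            local = local + offset
        ids.extend(layout)
        rows.append(local)
        comp_idx.extend([k] * len(layout))
    return ids, np.vstack(rows), np.asarray(comp_idx)


def spring_force(
    g_i: np.ndarray,
    g_j: np.ndarray,
    d_ij: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Hooke force on vertex i from the spring to vertex j with rest length d_ij.

    F_ij = (d_ij - ||g_i - g_j||) * (g_i - g_j)/||g_i - g_j||: repulsive when
    the spring is compressed, attractive when stretched.  Coincident endpoints
    get a random unit direction with magnitude d_ij (and a warning).
    """
    diff = np.asarray(g_i, dtype=float) - np.asarray(g_j, dtype=float)
    dist = float(np.hypot(*diff))
    if dist < COINCIDENT_EPS:
        warnings.warn("coincident vertices; substituting a random spring direction")
        rng = rng if rng is not None else np.random.default_rng()
        theta = rng.uniform(0.0, 2.0 * np.pi)
        return d_ij * np.array([np.cos(theta), np.sin(theta)])
    return (d_ij - dist) * diff / dist


def _pair_forces(
    positions: np.ndarray,
    comp_idx: np.ndarray,
    dmat: np.ndarray,
    rng: np.random.Generator | None = None,
    include_intra: bool = False,
) -> np.ndarray:
    """(n, n, 2) array of spring forces F[i, j] = force on i from j.

    Only inter-component pairs carry springs unless ``include_intra`` is set
    (used by the third-law equivalence test).  Antisymmetry F_ij = -F_ji is
    preserved also on the coincident-pair fallback.
    """
    n = len(positions)
    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    mask = np.ones((n, n), dtype=bool) if include_intra else comp_idx[:, None] != comp_idx[None, :]
    np.fill_diagonal(mask, False)
    coincident = mask & (dist < COINCIDENT_EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = np.where(dist[..., None] > 0, diff / np.where(dist == 0, 1.0, dist)[..., None], 0.0)
    forces = (dmat - dist)[..., None] * unit
    forces[~mask] = 0.0
    if coincident.any():
        warnings.warn("coincident vertices; substituting random spring directions")
        rng = rng if rng is not None else np.random.default_rng()
        iu, ju = np.where(np.triu(coincident))
        theta = rng.uniform(0.0, 2.0 * np.pi, size=len(iu))
        direction = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
        forces[iu, ju] = dmat[iu, ju, None] * direction
        forces[ju, iu] = -forces[iu, ju]
    return forces


def net_forces(
    layouts: list[dict[str, np.ndarray]],
    placement: ComponentPlacement,
    D: pd.DataFrame,
    rng: np.random.Generator | None = None,
    include_intra: bool = False,
) -> dict[str, np.ndarray]:
    """Net spring force on every vertex from all vertices of other components."""
    ids, positions, comp_idx = assemble_positions(layouts, placement)
    dmat = align_matrix(validate_dissimilarity(D), ids).to_numpy(dtype=float)
    forces = _pair_forces(positions, comp_idx, dmat, rng, include_intra).sum(axis=1)
    return {v: forces[i] for i, v in enumerate(ids)}


def component_update(
    k: int,
    forces: dict[str, np.ndarray],
    layouts: list[dict[str, np.ndarray]],
    placement: ComponentPlacement,
    params: SimulationParams,
) -> tuple[np.ndarray, float]:
    """Translation and rotation step (Delta c_k, Delta phi_k) for component k.

    Delta c_k is the mean force on the component's vertices times ``step_c``
    (the vertex mass cancels).  Delta phi_k is the net torque about the
    component centroid divided by the moment of inertia sum ||v_i||^2, times
    ``step_phi``; the torque arm is the *current rotated* local coordinate.
    Singletons have zero moment of inertia and never rotate.
    """
    layout = layouts[k]
    F = np.asarray([forces[v] for v in layout], dtype=float)
    local = np.asarray([layout[v] for v in layout], dtype=float)
    dc = params.step_c * F.sum(axis=0) / len(layout)
    inertia = float(np.sum(local**2))
    if inertia == 0.0:
        return dc, 0.0
    arms = local @ rotation_matrix(placement.angles[k]).T
    torque = float(np.sum(arms[:, 0] * F[:, 1] - arms[:, 1] * F[:, 0]))
    return dc, params.step_phi * torque / inertia


def total_stress(
    layouts: list[dict[str, np.ndarray]],
    placement: ComponentPlacement,
    D: pd.DataFrame,
) -> float:
    """Sum of squared spring residuals (d_ij - ||g_i - g_j||)^2 over inter-component pairs."""
    ids, positions, comp_idx = assemble_positions(layouts, placement)
    dmat = align_matrix(validate_dissimilarity(D), ids).to_numpy(dtype=float)
    dist = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    iu, ju = np.triu_indices(len(ids), k=1)
    inter = comp_idx[iu] != comp_idx[ju]
    resid = dmat[iu, ju][inter] - dist[iu, ju][inter]
    return float(np.sum(resid**2))


def _random_placement(
    p: int, scale: float, rng: np.random.Generator
) -> ComponentPlacement:
    centers = rng.uniform(-scale, scale, size=(p, 2))
    angles = rng.uniform(0.0, 2.0 * np.pi, size=p)
    return ComponentPlacement(centers=centers, angles=angles, scale=1.0)


def simulate_exact(
    layouts: list[dict[str, np.ndarray]],
    D: pd.DataFrame,
    params: SimulationParams | None = None,
    seed: int | None = None,
    init: ComponentPlacement | None = None,
) -> tuple[ComponentPlacement, list[tuple[int, float, float]]]:
    """Run the rigid-body spring simulation to (near-)equilibrium.

    Starts from ``init`` or a seeded random placement, iterates force
    evaluation and simultaneous component updates, and stops when the largest
    per-vertex force drops below ``force_tolerance`` or the iteration budget
    is exhausted.  Returns the final placement and a per-iteration log of
    ``(iteration, max_force, total_stress)``.
    """
    if not layouts:
        raise ValueError("at least one component required")
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    p = len(layouts)
    if init is not None:
        placement = ComponentPlacement(
            centers=init.centers.copy(), angles=init.angles.copy(), scale=init.scale
        )
    else:
        dvals = validate_dissimilarity(D).to_numpy(dtype=float)
        off = dvals[~np.eye(len(dvals), dtype=bool)]
        scale = float(off.mean()) if off.size else 1.0
        placement = _random_placement(p, max(scale, 1e-6), rng)

    ids, _, comp_idx = assemble_positions(layouts, placement)
    dmat = align_matrix(validate_dissimilarity(D), ids).to_numpy(dtype=float)
    sizes = np.asarray([len(layout) for layout in layouts], dtype=float)
    locals_per_comp = [
        np.asarray([layout[v] for v in layout], dtype=float) for layout in layouts
    ]
    inertia = np.asarray([float(np.sum(loc**2)) for loc in locals_per_comp])

    log: list[tuple[int, float, float]] = []
    for it in range(params.max_iterations):
        _, positions, _ = assemble_positions(layouts, placement)
        forces = _pair_forces(positions, comp_idx, dmat, rng).sum(axis=1)
        max_force = float(np.linalg.norm(forces, axis=1).max()) if len(forces) else 0.0
        dist = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
        iu, ju = np.triu_indices(len(ids), k=1)
        inter = comp_idx[iu] != comp_idx[ju]
        stress = float(np.sum((dmat[iu, ju][inter] - dist[iu, ju][inter]) ** 2))
        log.append((it, max_force, stress))
        if max_force < params.force_tolerance:
            break
        new_centers = placement.centers.copy()
        new_angles = placement.angles.copy()
        n_total = len(ids)
        for k in range(p):
            rows = comp_idx == k
            Fk = forces[rows]
            # Step constants are per spring: each vertex of component k feels
            # n_total - |V_k| springs, so the mean force grows linearly with
            # problem size; dividing keeps the stable step size-independent
            # (the proportionality constant in the update rule is free).
            n_partners = max(n_total - int(sizes[k]), 1)
            new_centers[k] += params.step_c * Fk.sum(axis=0) / sizes[k] / n_partners
            if inertia[k] > 0:
                arms = locals_per_comp[k] @ rotation_matrix(placement.angles[k]).T
                torque = float(np.sum(arms[:, 0] * Fk[:, 1] - arms[:, 1] * Fk[:, 0]))
                new_angles[k] += params.step_phi * torque / inertia[k] / n_partners
        if not (np.isfinite(new_centers).all() and np.isfinite(new_angles).all()):
            raise RuntimeError("step size too large")
        placement = ComponentPlacement(centers=new_centers, angles=new_angles, scale=1.0)
    return placement, log
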