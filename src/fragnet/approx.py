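"""Fast approximate component placement: MDS on component distances plus
annealed rotation.

Instead of simulating springs between all cross-component vertex pairs, the
approximation (i) collapses the vertex dissimilarities to a p x p matrix of
average-linkage component distances, (ii) embeds the p component centers in
the plane with SMACOF multidimensional scaling, (iii) fits a single scaling
factor K balancing component size against center spacing, and (iv) rotates
each component in place — translation stays fixed — using the same torque
rule as the exact simulation, with simulated annealing occasionally rotating
against the torque to escape local minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forces import ComponentPlacement, rotation_matrix
from .graph import align_matrix, validate_dissimilarity

__all__ = [
    "AnnealingSchedule",
    "component_distances",
    "smacof_mds",
    "classical_mds_init",
    "scaling_factor",
    "optimize_rotations",
]


@dataclass
class AnnealingSchedule:
    """Geometric cooling for the rotation phase.

    The temperature at sweep s is ``t0 * decay**s``; a component's torque step
    is reversed ("wrong direction") with probability exp(-1/T_s), which decays
    to zero.  ``t0 = 0`` is the greedy zero-temperature limit.
    """

    t0: float = 1.0
    decay: float = 0.9
    sweeps: int = 50
    seed: int | None = None
    step_phi: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.decay < 1.0:
            raise ValueError("decay must be in (0, 1)")
        if self.sweeps < 1:
            raise ValueError("sweeps must be >= 1")
        if self.t0 < 0:
            raise ValueError("t0 must be nonnegative")

    def reversal_probability(self, sweep: int) -> float:
        temperature = self.t0 * self.decay**sweep
        if temperature <= 0:
            return 0.0
        return float(np.exp(-1.0 / temperature))


def component_distances(
    D: pd.DataFrame, partition: list[list[str]]
) -> np.ndarray:
    """Average-linkage distance between components.

    delta_kl is the mean of d_ij over all cross pairs (v_i in V_k, v_j in
    V_l); the diagonal is zero.
    """
    validate_dissimilarity(D)
    all_ids = [v for block in partition for v in block]
    dmat = align_matrix(D, all_ids).to_numpy(dtype=float)
    p = len(partition)
    offsets = np.cumsum([0] + [len(b) for b in partition])
    delta = np.zeros((p, p))
    for k in range(p):
        rows = slice(offsets[k], offsets[k + 1])
        for l in range(k + 1, p):
            cols = slice(offsets[l], offsets[l + 1])
            delta[k, l] = delta[l, k] = float(dmat[rows, cols].mean())
    return delta


def _raw_stress(X: np.ndarray, delta: np.ndarray) -> float:
    dist = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    iu, ju = np.triu_indices(len(X), k=1)
    return float(np.sum((delta[iu, ju] - dist[iu, ju]) ** 2))


def classical_mds_init(delta: np.ndarray) -> np.ndarray:
    """Classical-scaling (Torgerson) start: double-centered squared distances,
    top-two eigenvectors scaled by the root eigenvalues."""
    p = len(delta)
    J = np.eye(p) - np.ones((p, p)) / p
    B = -0.5 * J @ (delta**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:2]
    w2 = np.clip(w[order], 0.0, None)
    X = V[:, order] * np.sqrt(w2)
    if X.shape[1] < 2:
        X = np.hstack([X, np.zeros((p, 2 - X.shape[1]))])
    return X


def smacof_mds(
    delta: np.ndarray,
    init: np.ndarray | None = None,
    seed: int | None = None,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> tuple[np.ndarray, list[float]]:
    """Embed component distances in the plane by SMACOF stress majorization.

    Iterates the Guttman transform, which guarantees the raw stress
    ``sum_{k<l} (delta_kl - ||c_k - c_l||)^2`` never increases; stops when the
    relative stress decrease falls below ``tol``.  Degenerate sizes are exact:
    one point maps to the origin, two points to (+-delta/2, 0).  Returns the
    (p, 2) centers and the per-iteration stress trace.
    """
    delta = np.asarray(delta, dtype=float)
    p = len(delta)
    if p == 1:
        return np.zeros((1, 2)), [0.0]
    if p == 2:
        half = delta[0, 1] / 2.0
        X = np.array([[-half, 0.0], [half, 0.0]])
        return X, [0.0]
    if init is not None:
        X = np.asarray(init, dtype=float).copy()
    else:
        rng = np.random.default_rng(seed)
        radius = np.sqrt(rng.uniform(0.0, 1.0, size=p))
        theta = rng.uniform(0.0, 2.0 * np.pi, size=p)
        X = np.stack([radius * np.cos(theta), radius * np.sin(theta)], axis=-1)
    trace = [_raw_stress(X, delta)]
    for _ in range(max_iter):
        dist = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, delta / np.where(dist == 0, 1.0, dist), 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / p
        stress = _raw_stress(X, delta)
        trace.append(stress)
        prev = trace[-2]
        if prev > 0 and (prev - stress) / prev < tol:
            break
        if prev == 0.0:
            break
    return X, trace


def scaling_factor(
    layouts: list[dict[str, np.ndarray]], centers: np.ndarray
) -> float:
    """K = v_bar / g_bar, the ratio of average component size to average
    center spacing.

    v_bar averages, over components with at least two vertices, the mean
    intra-component pairwise vertex distance; g_bar is the mean pairwise
    center distance.  Global positions then use ``g = R(phi) v + K c``, so K
    rescales the center spread relative to the fixed component sizes.  All
    components singletons (or a single component) degrades to K = 1 with a
    warning; coincident centers are an error.
    """
    import warnings

    centers = np.asarray(centers, dtype=float)
    p = len(centers)
    if p == 1:
        warnings.warn("single component; scaling factor defaults to 1")
        return 1.0
    sizes = []
    for layout in layouts:
        pts = np.asarray(list(layout.values()), dtype=float)
        if len(pts) < 2:
            continue
        diffs = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        iu, ju = np.triu_indices(len(pts), k=1)
        sizes.append(float(diffs[iu, ju].mean()))
    if not sizes:
        warnings.warn("all components are singletons; scaling factor defaults to 1")
        return 1.0
    v_bar = float(np.mean(sizes))
    iu, ju = np.triu_indices(p, k=1)
    g_bar = float(np.linalg.norm(centers[iu] - centers[ju], axis=-1).mean())
    if g_bar <= 0:
        raise ValueError("degenerate MDS solution: all centers coincide")
    return v_bar / g_bar


def _global_stress(
    positions: np.ndarray, comp_idx: np.ndarray, dmat: np.ndarray
) -> float:
    dist = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    iu, ju = np.triu_indices(len(positions), k=1)
    inter = comp_idx[iu] != comp_idx[ju]
    return float(np.sum((dmat[iu, ju][inter] - dist[iu, ju][inter]) ** 2))


def optimize_rotations(
    layouts: list[dict[str, np.ndarray]],
    centers: np.ndarray,
    K: float,
    D: pd.DataFrame,
    partition: list[list[str]] | None = None,
    schedule: AnnealingSchedule | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Rotate components in place to reduce spring stress, annealed.

    Each sweep visits components in ascending index order.  A component's
    torque-derived rotation step (same rule as the exact simulation, forces
    evaluated at the scaled positions ``R(phi)v + K c`` with unscaled rest
    lengths) is reversed with probability exp(-1/T); a reversed exploration
    move is always applied, a forward move only if the stress does not
    increase.  Centers and all intra-component geometry are untouched.
    Returns the angles and the stress trace (one entry per sweep plus the
    start).
    """
    schedule = schedule or AnnealingSchedule()
    rng = np.random.default_rng(schedule.seed)
    p = len(layouts)
    ids = [v for layout in layouts for v in layout]
    comp_idx = np.concatenate(
        [np.full(len(layout), k) for k, layout in enumerate(layouts)]
    )
    dmat = align_matrix(validate_dissimilarity(D), ids).to_numpy(dtype=float)
    locals_per_comp = [
        np.asarray([layout[v] for v in layout], dtype=float) for layout in layouts
    ]
    inertia = np.asarray([float(np.sum(loc**2)) for loc in locals_per_comp])
    centers = np.asarray(centers, dtype=float)
    angles = np.zeros(p)

    def positions_for(angles_now: np.ndarray) -> np.ndarray:
        rows = []
        for k in range(p):
            rows.append(
                locals_per_comp[k] @ rotation_matrix(angles_now[k]).T
                + K * centers[k]
            )
        return np.vstack(rows)

    positions = positions_for(angles)
    stress = _global_stress(positions, comp_idx, dmat)
    trace = [stress]
    row_of = {k: np.where(comp_idx == k)[0] for k in range(p)}
    for sweep in range(schedule.sweeps):
        p_rev = schedule.reversal_probability(sweep)
        for k in range(p):
            if inertia[k] == 0.0:
                continue
            rows = row_of[k]
            others = np.setdiff1d(np.arange(len(ids)), rows, assume_unique=True)
            diff = positions[rows][:, None, :] - positions[others][None, :, :]
            dist = np.linalg.norm(diff, axis=-1)
            safe = np.where(dist < 1e-12, 1.0, dist)
            F = ((dmat[np.ix_(rows, others)] - dist) / safe)[..., None] * diff
            Fk = F.sum(axis=1)
            arms = locals_per_comp[k] @ rotation_matrix(angles[k]).T
            torque = float(np.sum(arms[:, 0] * Fk[:, 1] - arms[:, 1] * Fk[:, 0]))
            # per-spring step normalization, as in the exact simulation
            dphi = schedule.step_phi * torque / inertia[k] / max(len(others), 1)
            reversed_move = rng.random() < p_rev
            if reversed_move:
                dphi = -dphi
            if dphi == 0.0:
                continue
            trial = angles.copy()
            trial[k] += dphi
            new_positions = positions.copy()
            new_positions[rows] = (
                locals_per_comp[k] @ rotation_matrix(trial[k]).T + K * centers[k]
            )
            new_stress = _global_stress(new_positions, comp_idx, dmat)
            if reversed_move or new_stress <= stress:
                angles = trial
                positions = new_positions
                stress = new_stress
        trace.append(stress)
    return angles, trace
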