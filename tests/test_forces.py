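"""Rigid-body spring model: forces, torques, updates, exact simulation."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_rigid_instance, random_dissimilarity
from fragnet.forces import (
    ComponentPlacement,
    SimulationParams,
    assemble_positions,
    component_update,
    global_position,
    net_forces,
    simulate_exact,
    spring_force,
    total_stress,
)


def brute_force_net_forces(layouts, placement, D, include_intra=False):
    """Independent double-loop evaluation of the per-vertex force sum."""
    ids, positions, comp_idx = assemble_positions(layouts, placement)
    pos = {v: positions[i] for i, v in enumerate(ids)}
    comp = {v: comp_idx[i] for i, v in enumerate(ids)}
    out = {}
    for vi in ids:
        total = np.zeros(2)
        for vj in ids:
            if vi == vj:
                continue
            if not include_intra and comp[vi] == comp[vj]:
                continue
            total += spring_force(pos[vi], pos[vj], D.loc[vi, vj])
        out[vi] = total
    return out


class TestGlobalPosition:
    def test_pure_translation(self):
        assert np.allclose(global_position([1, 0], 0.0, [2, 3], 1.0), [3, 3])

    def test_quarter_rotation(self):
        assert np.allclose(global_position([1, 0], np.pi / 2, [0, 0], 1.0), [0, 1], atol=1e-12)

    def test_center_scaling(self):
        assert np.allclose(global_position([1, 1], 0.0, [2, 2], 3.0), [7, 7])


class TestSpringForce:
    def test_rest_length_gives_zero_force(self):
        assert np.allclose(spring_force([0, 0], [1, 0], 1.0), [0, 0])

    def test_stretched_spring_attracts(self):
        f = spring_force([0, 0], [3, 0], 1.0)
        assert np.allclose(f, [2, 0])

    def test_antisymmetry(self, rng):
        for _ in range(100):
            gi, gj = rng.normal(size=(2, 2)) * 3
            d = float(rng.uniform(0, 4))
            fij = spring_force(gi, gj, d)
            fji = spring_force(gj, gi, d)
            assert np.allclose(fij, -fji, atol=1e-12)

    def test_coincident_points_guarded(self):
        with pytest.warns(UserWarning, match="coincident"):
            f = spring_force([1, 1], [1, 1], 2.0, rng=np.random.default_rng(0))
        assert np.linalg.norm(f) == pytest.approx(2.0)


class TestNetForces:
    def test_two_singletons_at_rest(self):
        layouts = [{"a": np.zeros(2)}, {"b": np.zeros(2)}]
        placement = ComponentPlacement([[0, 0], [5, 0]], [0, 0])
        D = pd.DataFrame(
            [[0, 5.0], [5.0, 0]], index=["a", "b"], columns=["a", "b"]
        )
        forces = net_forces(layouts, placement, D)
        assert np.allclose(forces["a"], 0) and np.allclose(forces["b"], 0)

    def test_symmetric_square_is_equilibrium(self):
        ids = ["a", "b", "c", "d"]
        layouts = [{v: np.zeros(2)} for v in ids]
        centers = [[0, 0], [1, 0], [1, 1], [0, 1]]
        placement = ComponentPlacement(centers, np.zeros(4))
        s, diag = 1.0, np.sqrt(2.0)
        vals = [
            [0, s, diag, s],
            [s, 0, s, diag],
            [diag, s, 0, s],
            [s, diag, s, 0],
        ]
        D = pd.DataFrame(vals, index=ids, columns=ids)
        forces = net_forces(layouts, placement, D)
        for v in ids:
            assert np.allclose(forces[v], 0, atol=1e-12)

    def test_matches_bruteforce(self, rng):
        for _ in range(5):
            layouts, placement, D = random_rigid_instance(rng, n_components=3)
            fast = net_forces(layouts, placement, D)
            slow = brute_force_net_forces(layouts, placement, D)
            for v in fast:
                assert np.allclose(fast[v], slow[v], atol=1e-12)


class TestComponentUpdate:
    def test_zero_forces_fixed_point(self):
        layouts = [{"a": np.array([1.0, 0]), "b": np.array([-1.0, 0])}]
        placement = ComponentPlacement([[0, 0]], [0.0])
        params = SimulationParams(step_c=1, step_phi=1)
        dc, dphi = component_update(
            0, {"a": np.zeros(2), "b": np.zeros(2)}, layouts, placement, params
        )
        assert np.allclose(dc, 0) and dphi == 0.0

    def test_singleton_translates_without_rotation(self):
        layouts = [{"a": np.zeros(2)}]
        placement = ComponentPlacement([[0, 0]], [0.0])
        params = SimulationParams(step_c=1, step_phi=1)
        dc, dphi = component_update(0, {"a": np.array([2.0, 0])}, layouts, placement, params)
        assert np.allclose(dc, [2, 0]) and dphi == 0.0

    def test_pure_torque_couple(self):
        # forces (0,+1) at (1,0) and (0,-1) at (-1,0): zero net force,
        # torque 2, inertia 2 -> one radian per unit step
        layouts = [{"a": np.array([1.0, 0]), "b": np.array([-1.0, 0])}]
        placement = ComponentPlacement([[0, 0]], [0.0])
        params = SimulationParams(step_c=1, step_phi=1)
        forces = {"a": np.array([0.0, 1.0]), "b": np.array([0.0, -1.0])}
        dc, dphi = component_update(0, forces, layouts, placement, params)
        assert np.allclose(dc, 0, atol=1e-12)
        assert dphi == pytest.approx(1.0)

    def test_third_law_intra_pairs_change_nothing(self, rng):
        params = SimulationParams(step_c=0.3, step_phi=0.3)
        for _ in range(10):
            layouts, placement, D = random_rigid_instance(rng)
            inter = net_forces(layouts, placement, D)
            both = net_forces(layouts, placement, D, include_intra=True)
            for k in range(len(layouts)):
                dc1, dphi1 = component_update(k, inter, layouts, placement, params)
                dc2, dphi2 = component_update(k, both, layouts, placement, params)
                assert np.allclose(dc1, dc2, atol=1e-9)
                assert dphi1 == pytest.approx(dphi2, abs=1e-9)

    def test_translational_invariance(self, rng):
        params = SimulationParams()
        layouts, placement, D = random_rigid_instance(rng, n_components=3)
        shifted = ComponentPlacement(
            placement.centers + np.array([13.7, -2.2]), placement.angles.copy()
        )
        f1 = net_forces(layouts, placement, D)
        f2 = net_forces(layouts, shifted, D)
        for v in f1:
            assert np.allclose(f1[v], f2[v], atol=1e-9)
        for k in range(len(layouts)):
            u1 = component_update(k, f1, layouts, placement, params)
            u2 = component_update(k, f2, layouts, shifted, params)
            assert np.allclose(u1[0], u2[0], atol=1e-9)
            assert u1[1] == pytest.approx(u2[1], abs=1e-9)


class TestTotalStress:
    def test_exact_realization_has_zero_stress(self):
        layouts = [{"a": np.zeros(2)}, {"b": np.zeros(2)}]
        placement = ComponentPlacement([[0, 0], [2, 0]], [0, 0])
        D = pd.DataFrame([[0, 2.0], [2.0, 0]], index=["a", "b"], columns=["a", "b"])
        assert total_stress(layouts, placement, D) == 0.0

    def test_unit_residual(self):
        layouts = [{"a": np.zeros(2)}, {"b": np.zeros(2)}]
        placement = ComponentPlacement([[0, 0], [1, 0]], [0, 0])
        D = pd.DataFrame([[0, 2.0], [2.0, 0]], index=["a", "b"], columns=["a", "b"])
        assert total_stress(layouts, placement, D) == pytest.approx(1.0)

    def test_matches_bruteforce(self, rng):
        for _ in range(5):
            layouts, placement, D = random_rigid_instance(rng)
            ids, positions, comp_idx = assemble_positions(layouts, placement)
            slow = 0.0
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    if comp_idx[i] == comp_idx[j]:
                        continue
                    dist = np.linalg.norm(positions[i] - positions[j])
                    slow += (D.loc[ids[i], ids[j]] - dist) ** 2
            assert total_stress(layouts, placement, D) == pytest.approx(slow, abs=1e-10)


class TestSimulateExact:
    def test_single_component_unchanged(self, rng):
        pts = rng.normal(size=(4, 2))
        pts -= pts.mean(axis=0)
        layouts = [{f"v{i}": pts[i] for i in range(4)}]
        D = random_dissimilarity([f"v{i}" for i in range(4)], rng)
        init = ComponentPlacement([[1.5, -2.0]], [0.3])
        placement, log = simulate_exact(layouts, D, seed=0, init=init)
        assert np.allclose(placement.centers, init.centers)
        assert placement.angles[0] == init.angles[0]
        assert len(log) == 1  # converged immediately: no inter-component springs

    def test_two_singletons_reach_rest_length(self):
        layouts = [{"a": np.zeros(2)}, {"b": np.zeros(2)}]
        D = pd.DataFrame([[0, 5.0], [5.0, 0]], index=["a", "b"], columns=["a", "b"])
        placement, _ = simulate_exact(layouts, D, seed=1)
        dist = np.linalg.norm(placement.centers[0] - placement.centers[1])
        assert dist == pytest.approx(5.0, abs=1e-3)

    def test_345_triangle_realized(self):
        ids = ["a", "b", "c"]
        layouts = [{v: np.zeros(2)} for v in ids]
        vals = [[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]]
        D = pd.DataFrame(vals, index=ids, columns=ids)
        placement, _ = simulate_exact(layouts, D, seed=2)
        c = placement.centers
        assert np.linalg.norm(c[0] - c[1]) == pytest.approx(3.0, abs=1e-2)
        assert np.linalg.norm(c[0] - c[2]) == pytest.approx(4.0, abs=1e-2)
        assert np.linalg.norm(c[1] - c[2]) == pytest.approx(5.0, abs=1e-2)

    def test_zero_force_configuration_is_fixed_point(self):
        layouts = [{"a": np.zeros(2)}, {"b": np.zeros(2)}]
        D = pd.DataFrame([[0, 4.0], [4.0, 0]], index=["a", "b"], columns=["a", "b"])
        init = ComponentPlacement([[0, 0], [4.0, 0]], [0, 0])
        placement, log = simulate_exact(layouts, D, seed=3, init=init)
        assert np.array_equal(placement.centers, init.centers)
        assert len(log) == 1

    def test_stress_non_increasing_with_small_steps(self, rng):
        layouts, _, D = random_rigid_instance(rng, n_components=5)
        params = SimulationParams(step_c=0.02, step_phi=0.02, max_iterations=300)
        _, log = simulate_exact(layouts, D, params=params, seed=4)
        stresses = [row[2] for row in log]
        diffs = np.diff(stresses)
        assert np.all(diffs <= 1e-9)

    def test_iteration_log_shape(self, rng):
        layouts, _, D = random_rigid_instance(rng, n_components=3)
        _, log = simulate_exact(
            layouts, D, params=SimulationParams(max_iterations=50), seed=5
        )
        assert all(len(row) == 3 for row in log)
        assert [row[0] for row in log] == list(range(len(log)))
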