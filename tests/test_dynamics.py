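"""Friction operator, conjugate-gradient solve and time stepping."""

import numpy as np
import pytest

from mdcell.contact import MDParams, Plane
from mdcell.cortex import CortexParams
from mdcell.dynamics import (DynamicsParams, Simulation, assemble_friction,
                             solve_velocities)
from mdcell.mesh import RestState, icosphere

R = 3.25e-6


def _free_system(mesh, dyn=None, cortex=None):
    return assemble_friction(mesh, [], dyn or DynamicsParams(),
                             cortex or CortexParams(),
                             RestState.from_mesh(mesh))


class TestFrictionSystem:
    def test_free_cell_recovers_stokes_velocity(self):
        """Uniform force on all nodes must translate the cell rigidly at
        exactly the Stokes velocity of the whole sphere."""
        mesh = icosphere(1, R)
        dyn = DynamicsParams()
        system = _free_system(mesh, dyn)
        F = np.zeros_like(mesh.nodes)
        F[:, 0] = 1e-12
        v = solve_velocities(F, system, e_max=1e-16)
        v_stokes = F[:, 0].sum() / (6 * np.pi * dyn.eta * dyn.r_cell)
        np.testing.assert_allclose(v[:, 0], v_stokes, rtol=1e-4)
        assert np.abs(v[:, 1:]).max() < 1e-4 * v_stokes

    def test_operator_is_symmetric(self, rng, sphere_162):
        system = _free_system(sphere_162)
        n = 3 * sphere_162.n_nodes
        for _ in range(5):
            u, v = rng.standard_normal(n), rng.standard_normal(n)
            lhs = u @ system.matvec(v)
            rhs = v @ system.matvec(u)
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_operator_is_positive_definite(self, rng, sphere_162):
        system = _free_system(sphere_162)
        n = 3 * sphere_162.n_nodes
        for _ in range(100):
            v = rng.standard_normal(n)
            assert v @ system.matvec(v) > 0

    def test_matrix_free_equals_assembled(self, rng, sphere_162):
        # with substrate contact so every block type is present
        mesh = sphere_162.copy()
        mesh.nodes[:, 2] -= mesh.nodes[:, 2].min() + 0.005 * R  # indent
        sim = Simulation(mesh, plane=Plane())
        _, _, patches = sim.total_conservative_force()
        assert patches
        system = assemble_friction(mesh, patches, sim.dyn, sim.cortex,
                                   sim.state.rest)
        G = system.assemble()
        v = rng.standard_normal(G.shape[0])
        np.testing.assert_allclose(system.matvec(v), G @ v,
                                   rtol=1e-12, atol=1e-30)

    def test_contact_increases_dissipation(self, sphere_162, rng):
        mesh = sphere_162.copy()
        mesh.nodes[:, 2] -= mesh.nodes[:, 2].min() + 0.005 * R  # indent
        sim = Simulation(mesh, plane=Plane())
        _, _, patches = sim.total_conservative_force()
        free = assemble_friction(mesh, [], sim.dyn, sim.cortex, sim.state.rest)
        full = assemble_friction(mesh, patches, sim.dyn, sim.cortex,
                                 sim.state.rest)
        v = rng.standard_normal(3 * mesh.n_nodes)
        assert v @ full.matvec(v) > v @ free.matvec(v)


class TestSolveVelocities:
    def test_diagonal_system_solved_exactly(self):
        mesh = icosphere(1, R)
        system = _free_system(mesh, cortex=CortexParams(c_damp=0.0))
        F = np.arange(3.0 * mesh.n_nodes).reshape(-1, 3) * 1e-14
        v = solve_velocities(F, system, e_max=1e-18)
        np.testing.assert_allclose(v, F / system.stokes, rtol=1e-10)

    def test_matches_dense_direct_solve(self, rng):
        mesh = icosphere(0, R)           # the 12-node icosahedron
        system = _free_system(mesh)
        F = rng.standard_normal((12, 3)) * 1e-12
        v = solve_velocities(F, system, e_max=1e-18)
        dense = np.linalg.solve(system.assemble().toarray(), F.ravel())
        np.testing.assert_allclose(v.ravel(), dense, rtol=1e-10)

    def test_warm_start_reaches_same_solution(self, rng):
        mesh = icosphere(1, R)
        system = _free_system(mesh)
        F = rng.standard_normal((mesh.n_nodes, 3)) * 1e-12
        cold = solve_velocities(F, system, e_max=1e-18)
        warm = solve_velocities(F, system, e_max=1e-18,
                                x0=cold + rng.standard_normal(cold.shape) * 1e-6)
        np.testing.assert_allclose(warm, cold, rtol=1e-6)


class TestStepping:
    def test_rest_sphere_is_equilibrium(self, sphere_162):
        sim = Simulation(sphere_162.copy())
        F, contrib, _ = sim.total_conservative_force()
        scale = CortexParams().ks * RestState.from_mesh(sphere_162).L0.mean()
        assert np.abs(F).max() < 1e-9 * scale
        before = sim.state.mesh.nodes.copy()
        sim.step()
        np.testing.assert_allclose(sim.state.mesh.nodes, before,
                                   atol=1e-12 * R)

    def test_contributions_sum_to_total(self, biconcave_162):
        mesh = biconcave_162.copy()
        mesh.nodes[:, 0] *= 1.05
        sim = Simulation(mesh, rest=RestState.from_mesh(biconcave_162))
        F, contrib, _ = sim.total_conservative_force()
        np.testing.assert_allclose(F, sum(contrib.values()), rtol=1e-12)

    def test_nan_contribution_is_reported(self, sphere_162):
        sim = Simulation(sphere_162.copy())
        sim.external_force = lambda state: np.full_like(state.mesh.nodes, np.nan)
        with pytest.raises(Exception, match="external"):
            sim.total_conservative_force()

    def test_energy_bookkeeping_first_order(self, sphere_162):
        """Work done by the elastic forces matches the elastic-energy loss
        to first order in dt (dissipation equals applied work exactly by
        construction of the overdamped solve)."""
        from mdcell.cortex import elastic_energy

        mesh = sphere_162.copy()
        center = mesh.nodes.mean(axis=0)
        mesh.nodes[:] = center + (mesh.nodes - center) * 1.005  # inflate 0.5 %
        rest = RestState.from_mesh(sphere_162)
        # penalty-only physics: the audit accounts conservative forces, so
        # the exact volume constraint (which does unaccounted work) is off
        sim = Simulation(mesh, rest=rest,
                         dyn=DynamicsParams(volume_projection=False))
        dt = 1e-6
        W_el = 0.0
        E0 = elastic_energy(sim.state.mesh, rest, sim.cortex)
        for _ in range(20):
            F, contrib, _ = sim.total_conservative_force()
            f_el = (contrib["fene"] + contrib["bending"] + contrib["area"]
                    + contrib["volume"])
            sim.step(dt)
            W_el += float(np.einsum("ij,ij->", f_el, sim.state.velocities)) * dt
        E1 = elastic_energy(sim.state.mesh, rest, sim.cortex)
        assert W_el == pytest.approx(E0 - E1, rel=0.05)

    def test_dissipation_nonnegative_each_step(self, sphere_162):
        mesh = sphere_162.copy()
        mesh.nodes[:, 2] *= 1.03
        sim = Simulation(mesh, rest=RestState.from_mesh(sphere_162))
        for _ in range(5):
            F, _, patches = sim.total_conservative_force()
            system = assemble_friction(sim.state.mesh, patches, sim.dyn,
                                       sim.cortex, sim.state.rest)
            sim.step()
            v = sim.state.velocities.ravel()
            assert v @ system.matvec(v) >= 0

    def test_timestep_guard_aborts_on_explosive_force(self, sphere_162):
        sim = Simulation(sphere_162.copy())
        sim.external_force = lambda state: np.full_like(state.mesh.nodes, 1e-6)
        with pytest.raises(Exception, match="displacement|reduce dt"):
            sim.step()

    def test_dt_refinement_converges(self):
        """Halving dt changes the short-run spreading curve by < 2 %."""
        def run(dt):
            mesh = icosphere(2, R, center=(0, 0, R + 10e-9))
            sim = Simulation(mesh, plane=Plane(), dyn=DynamicsParams(dt=dt))
            rc = []
            sim.run(4.8e-3, observer=lambda st: rc.append(sim.contact_radius()),
                    observe_every=max(int(round(2.4e-4 / dt)), 1))
            return np.asarray(rc)

        r1, r2 = run(2.4e-5), run(1.2e-5)
        n = min(len(r1), len(r2))
        scale = r1[:n].max()
        assert np.abs(r1[:n] - r2[:n]).max() < 0.02 * scale

    def test_pinning_leaves_spreading_unchanged(self):
        """A very high pin friction on fully-contacting nodes damps their
        motion without altering the contact-radius curve."""
        def run(factor):
            mesh = icosphere(2, R, center=(0, 0, R + 10e-9))
            dyn = DynamicsParams(dt=2.4e-5, gamma_fix_factor=factor)
            sim = Simulation(mesh, plane=Plane(), dyn=dyn)
            rc = []
            sim.run(7.2e-3, observer=lambda st: rc.append(sim.contact_radius()),
                    observe_every=20)
            return np.asarray(rc), sim

        r_off, _ = run(0.0)
        r_on, sim_on = run(1e3)
        scale = max(r_off.max(), r_on.max())
        assert np.abs(r_on - r_off).max() < 0.01 * scale
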