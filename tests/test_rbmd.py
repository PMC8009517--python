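"""Rigid-body MD: fragment setup, momentum sampling, the quaternion
velocity-Verlet propagator, RATTLE, the rough wall and ensemble drivers."""

import numpy as np
import pytest

from conftest import lj_particle, make_droplet
from nanospec import rbmd
from nanospec import quatcore as qc
from nanospec.ffield import ForceTorqueSet, FragmentTopology, PairForceField
from nanospec.units import KB_INTERNAL, KJ_PER_INTERNAL


def zero_ff(n_fragments):
    """Force provider for free (non-interacting) fragments."""
    class _Z:
        def evaluate(self, positions):
            return ForceTorqueSet(
                0.0,
                np.zeros_like(positions),
                np.zeros((n_fragments, 3)),
                np.zeros((n_fragments, 3)),
            )

    return _Z()


def asymmetric_top():
    return FragmentTopology(
        "tri", ["A", "B", "C"], [12.0, 1.0, 16.0], [0, 0, 0], [1, 1, 1], [0, 0, 0],
        [[0.0, 0, 0], [1.1, 0, 0], [0.3, 1.2, 0]], rigid=True,
    )


class TestInitFragment:
    def test_homonuclear_diatomic_moments(self):
        m, d = 7.0, 1.4
        with pytest.warns(UserWarning, match="linear"):
            moments, _q, canon = rbmd.init_fragment(
                [[-d / 2, 0, 0], [d / 2, 0, 0]], [m, m]
            )
        # two transverse moments m d^2 / 2, one vanishing axial moment
        assert np.isclose(moments[0], 0.0)
        assert np.allclose(moments[1:], m * d**2 / 2)
        assert np.allclose(np.linalg.norm(canon, axis=1), d / 2)

    def test_triatomic_moments_match_bruteforce_eigenvalues(self):
        coords = np.array([[0.0, 0, 0], [1.1, 0, 0], [0.3, 1.2, 0]])
        masses = np.array([12.0, 1.0, 16.0])
        moments, _q, _c = rbmd.init_fragment(coords, masses)
        com = masses @ coords / masses.sum()
        r = coords - com
        inertia = np.einsum("a,ai,aj->ij", masses, r, r)
        inertia = np.trace(inertia) * np.eye(3) - inertia
        ref = np.linalg.eigvalsh(inertia)
        assert np.allclose(moments, ref, atol=1e-10)

    def test_single_atom_is_degenerate_rotor(self):
        with pytest.raises(rbmd.DegenerateRotorError):
            rbmd.init_fragment([[0.0, 0, 0]], [12.0])

    def test_canonical_frame_reproduces_input_geometry(self):
        topo = asymmetric_top()
        moments, q0, canon = rbmd.init_fragment(topo.local_coords, topo.masses)
        com = topo.masses @ topo.local_coords / topo.total_mass
        rebuilt = com + qc.quat_rotate(q0, canon, qc.MF_TO_LF)
        assert np.allclose(rebuilt, topo.local_coords, atol=1e-10)


class TestSampleMomenta:
    def test_zero_temperature_gives_zero_motion(self, acn_topology, rng):
        state = rbmd.build_state([acn_topology], [0, 0], np.array([[0.0, 0, 0], [8.0, 0, 0]]))
        state = rbmd.sample_momenta(state, 0.0, rng)
        assert np.abs(state.vcom).max() == 0.0
        assert np.abs(state.ang_mom).max() == 0.0

    def test_kinetic_energies_hit_target_exactly(self, acn_topology, rng):
        coms = np.array([[0.0, 0, 0], [8.0, 0, 0], [0, 8.0, 0]])
        state = rbmd.build_state([acn_topology], [0, 0, 0], coms)
        T = 250.0
        state = rbmd.sample_momenta(state, T, rng)
        e_tr, e_rot = state.kinetic_energies()
        kt = KB_INTERNAL * T * KJ_PER_INTERNAL
        assert np.isclose(e_tr, 0.5 * state.translational_dof * kt, rtol=1e-12)
        assert np.isclose(e_rot, 0.5 * state.rotational_dof * kt, rtol=1e-12)
        # net linear momentum removed
        p = state.rigid_mass @ state.vcom
        assert np.abs(p).max() < 1e-9

    def test_two_seeds_same_energy_different_momenta(self, acn_topology):
        coms = np.array([[0.0, 0, 0], [8.0, 0, 0]])
        state = rbmd.build_state([acn_topology], [0, 0], coms)
        s1 = rbmd.sample_momenta(state, 300.0, np.random.default_rng(1))
        s2 = rbmd.sample_momenta(state, 300.0, np.random.default_rng(2))
        assert not np.allclose(s1.vcom, s2.vcom)
        assert np.isclose(
            sum(s1.kinetic_energies()), sum(s2.kinetic_energies()), rtol=1e-12
        )


class TestFreeRotor:
    def test_symmetric_top_spinning_about_symmetry_axis(self):
        # square of equal masses: principal moments (I, I, 2I); spin about z
        topo = FragmentTopology(
            "sq", list("ABCD"), [2.0] * 4, [0] * 4, [1] * 4, [0] * 4,
            [[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]], rigid=True,
        )
        state = rbmd.build_state([topo], [0], np.zeros((1, 3)))
        omega = 3.0  # rad/ps about the symmetry (z) axis
        iz = state.inertia[0, 2]
        state.ang_mom[0] = qc.quat_rotate(state.quat[0], [0, 0, iz * omega])
        settings = rbmd.IntegratorSettings(dt_fs=1.0, quat_tol=1e-13)
        n = 400
        x = state
        for _ in range(n):
            x, _, _ = rbmd.rvv1_step(x, zero_ff(1), settings)
        # |L| exactly conserved; rotation angle = omega * t
        assert np.isclose(
            np.linalg.norm(x.ang_mom[0]), iz * omega, rtol=1e-12
        )
        dq = qc.quat_multiply(qc.quat_conjugate(state.quat[0]), x.quat[0])
        angle = 2 * np.arctan2(np.linalg.norm(dq[1:]), abs(dq[0]))
        expected = (omega * n * 1e-3) % (2 * np.pi)
        expected = min(expected, 2 * np.pi - expected)  # double cover folding
        assert np.isclose(angle, expected, atol=1e-6)

    def test_asymmetric_top_conserves_energy_and_momentum(self):
        topo = asymmetric_top()
        state = rbmd.build_state([topo], [0], np.zeros((1, 3)))
        state = rbmd.sample_momenta(state, 300.0, np.random.default_rng(7))
        state.vcom[:] = 0.0
        settings = rbmd.IntegratorSettings(dt_fs=2.0, quat_tol=1e-13)
        res = rbmd.run_md(state, zero_ff(1), settings, ensemble="NVE", n_steps=2500)
        e = res.diagnostics["E_kin_rot"].to_numpy()
        assert np.abs(e - e[0]).max() / e[0] < 5e-5
        l0 = np.linalg.norm(state.ang_mom[0])
        lf = np.linalg.norm(res.final_state.ang_mom[0])
        assert np.isclose(lf, l0, rtol=1e-12)

    def test_asymmetric_top_matches_fine_step_reference(self):
        # orientation after 1 ps at dt vs a dt/20 reference: second-order error
        topo = asymmetric_top()
        state = rbmd.build_state([topo], [0], np.zeros((1, 3)))
        state = rbmd.sample_momenta(state, 300.0, np.random.default_rng(9))
        state.vcom[:] = 0.0

        def final_quat(dt_fs, n):
            s = rbmd.IntegratorSettings(dt_fs=dt_fs, quat_tol=1e-14, max_quat_iter=500)
            x = state
            for _ in range(n):
                x, _, _ = rbmd.rvv1_step(x, zero_ff(1), s)
            return x.quat[0]

        q_ref = final_quat(0.1, 10000)
        err_coarse = np.linalg.norm(final_quat(2.0, 500) - q_ref)
        err_fine = np.linalg.norm(final_quat(0.5, 2000) - q_ref)
        assert err_fine < err_coarse / 8  # consistent with O(dt^2) convergence

    def test_zero_omega_converges_in_one_iteration(self, acn_topology):
        state = rbmd.build_state([acn_topology], [0], np.zeros((1, 3)))
        settings = rbmd.IntegratorSettings(dt_fs=1.0, quat_tol=1e-12)
        new, iters, _ = rbmd.rvv1_step(state, zero_ff(1), settings)
        assert iters == 1
        assert np.allclose(new.quat, state.quat)


class TestRattle:
    def test_constrained_diatomic_free_flight(self):
        topo = FragmentTopology(
            "di", ["A", "B"], [2.0, 3.0], [0, 0], [1, 1], [0, 0],
            [[0, 0, 0], [1.5, 0, 0]], rigid=False, constraints=[(0, 1, 1.5)],
        )
        state = rbmd.build_state([topo], [0], np.zeros((1, 3)))
        state = rbmd.sample_momenta(state, 200.0, np.random.default_rng(4))
        settings = rbmd.IntegratorSettings(dt_fs=1.0)
        x = state
        for _ in range(300):
            x = rbmd.rattle_step(x, zero_ff(1), settings)
        d = np.linalg.norm(x.positions[0] - x.positions[1])
        assert abs(d - 1.5) < 1e-8
        # velocity orthogonal to the constraint gradient: d/dt(r_ij^2) = 0
        rij = x.positions[0] - x.positions[1]
        vij = x.flex_vel[0] - x.flex_vel[1]
        assert abs(rij @ vij) < 1e-8
        # COM in uniform free flight
        com = x.fragment_coms()[0]
        m = np.array([2.0, 3.0])
        v_com0 = m @ state.flex_vel / m.sum()
        assert np.allclose(com, v_com0 * 0.3, atol=1e-9)

    def test_empty_constraints_reduce_to_velocity_verlet(self):
        # two LJ atoms propagated by the engine vs a hand-coded VV loop
        lj = lj_particle()
        coms = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        state = rbmd.build_state([lj, lj], [0, 1], coms)
        state.flex_vel[:] = [[0.5, 0, 0], [-0.5, 0, 0]]
        ff = PairForceField([lj, lj], [0, 1])
        settings = rbmd.IntegratorSettings(dt_fs=0.5)
        x = state
        for _ in range(50):
            x = rbmd.rattle_step(x, ff, settings)

        # independent oracle: plain velocity Verlet on the same Hamiltonian
        pos = coms.copy()
        vel = np.array([[0.5, 0, 0], [-0.5, 0, 0]])
        dt = 0.5e-3
        f = ff.evaluate(pos).atom_forces * 100.0  # amu Å/ps²
        for _ in range(50):
            vel += 0.5 * dt * f
            pos += dt * vel
            f = ff.evaluate(pos).atom_forces * 100.0
            vel += 0.5 * dt * f
        assert np.abs(x.positions - pos).max() < 1e-10
        assert np.abs(x.flex_vel - vel).max() < 1e-10


class TestRoughWall:
    def test_inside_fragments_untouched(self, acn_topology, rng):
        state = rbmd.build_state([acn_topology], [0], np.zeros((1, 3)))
        state = rbmd.sample_momenta(state, 300.0, rng)
        out = rbmd.rough_wall(state, 10.0, 300.0, rng)
        assert np.allclose(out.vcom, state.vcom)
        assert np.allclose(out.ang_mom, state.ang_mom)

    def test_escaped_fragment_gets_inward_velocity(self, acn_topology):
        state = rbmd.build_state([acn_topology], [0], np.array([[12.0, 3.0, -4.0]]))
        rng = np.random.default_rng(0)
        state = rbmd.sample_momenta(state, 300.0, rng)
        for trial in range(20):
            out = rbmd.rough_wall(state, 10.0, 300.0, rng)
            rhat = out.com[0] / np.linalg.norm(out.com[0])
            assert out.vcom[0] @ rhat < 0.0

    def test_confined_run_never_escapes_far(self):
        lj = lj_particle()
        n, radius = 30, 3.0
        from nanospec.fixio import pack_droplet

        coms, _ = pack_droplet(n, radius - 0.2, 0.9, lj, seed=5)
        state = rbmd.build_state([lj] * 1, np.zeros(n, dtype=int), coms)
        ff = PairForceField([lj], np.zeros(n, dtype=int))
        T = 180.0
        rng = np.random.default_rng(5)
        state = rbmd.sample_momenta(state, T, rng)
        settings = rbmd.IntegratorSettings(
            dt_fs=0.4, temperature=T, tau_ps=0.05, boundary_radius=radius
        )
        max_r = 0.0

        def watch(st, i):
            nonlocal max_r
            max_r = max(max_r, np.linalg.norm(st.positions, axis=1).max())

        rbmd.run_md(state, ff, settings, ensemble="NVT", n_steps=4000,
                    observers=[watch], rng=rng)
        assert max_r < radius + 2.0


class TestEnsembles:
    def test_noninteracting_rigid_gas_conserves_energy(self, acn_topology):
        coms = np.array([[0.0, 0, 0], [9.0, 0, 0], [0, 9.0, 0]])
        state = rbmd.build_state([acn_topology], [0, 0, 0], coms)
        state = rbmd.sample_momenta(state, 300.0, np.random.default_rng(2))
        settings = rbmd.IntegratorSettings(dt_fs=0.1, quat_tol=1e-13)
        res = rbmd.run_md(state, zero_ff(3), settings, ensemble="NVE", n_steps=500)
        e = res.diagnostics["E_tot"].to_numpy()
        assert np.abs(e - e[0]).max() / abs(e[0]) < 1e-6

    def test_berendsen_identity_when_already_at_target(self, acn_topology):
        coms = np.array([[0.0, 0, 0], [9.0, 0, 0]])
        state = rbmd.build_state([acn_topology], [0, 0], coms)
        state = rbmd.sample_momenta(state, 300.0, np.random.default_rng(3))
        assert np.isclose(state.temperature(), 300.0, rtol=1e-12)
        settings = rbmd.IntegratorSettings(dt_fs=1.0, temperature=300.0)
        res_nvt = rbmd.run_md(state.copy(), zero_ff(2), settings, "NVT", n_steps=1)
        res_nve = rbmd.run_md(state.copy(), zero_ff(2), settings, "NVE", n_steps=1)
        assert np.allclose(res_nvt.final_state.vcom, res_nve.final_state.vcom, rtol=1e-12)

    def test_fluctuation_and_iterations_ordered_in_time_step(self, small_droplet):
        state, ff = small_droplet
        # settle briefly so the window is not dominated by relaxation
        pre = rbmd.IntegratorSettings(dt_fs=0.5, quat_tol=1e-12)
        eq = rbmd.run_md(state, ff, pre, "NVE", n_steps=600).final_state
        devs, iters = [], []
        for dt in [0.5, 1.0, 2.0, 4.0]:
            settings = rbmd.IntegratorSettings(dt_fs=dt, quat_tol=1e-13)
            res = rbmd.run_md(eq.copy(), ff, settings, "NVE", n_steps=int(200 / dt))
            e = res.diagnostics["E_tot"].to_numpy()
            devs.append(np.abs(e - e.mean()).max() / abs(e.mean()))
            iters.append(res.diagnostics["max_iters"].mean())
        assert devs == sorted(devs), f"energy deviation not monotone in dt: {devs}"
        assert iters == sorted(iters), f"iteration count not monotone in dt: {iters}"

    def test_linear_and_angular_momentum_conserved(self, small_droplet):
        state, ff = small_droplet
        settings = rbmd.IntegratorSettings(dt_fs=0.1, quat_tol=1e-14, max_quat_iter=500)
        res = rbmd.run_md(state.copy(), ff, settings, "NVE", n_steps=100)
        fin = res.final_state

        def total_p(st):
            return st.rigid_mass @ st.vcom

        def total_l(st):
            spin = st.ang_mom.sum(axis=0)
            orbital = np.sum(
                st.rigid_mass[:, None] * np.cross(st.com, st.vcom), axis=0
            )
            return spin + orbital

        p0, pf = total_p(state), total_p(fin)
        l0, lf = total_l(state), total_l(fin)
        assert np.abs(pf - p0).max() <= 1e-8 * max(np.linalg.norm(p0), 1.0)
        assert np.abs(lf - l0).max() <= 1e-8 * np.linalg.norm(l0)

    def test_temperature_has_no_systematic_drift_in_nve(self, acn_topology):
        # cold enough that a 10-molecule droplet does not evaporate on the
        # test's time scale; thermostat-equilibrated before the NVE window
        state, ff = make_droplet(acn_topology, 10, 7.5, seed=21, temperature=150.0)
        nvt = rbmd.IntegratorSettings(
            dt_fs=1.0, temperature=150.0, tau_ps=0.2, boundary_radius=9.0
        )
        eq = rbmd.run_md(state, ff, nvt, "NVT", n_steps=4000,
                         rng=np.random.default_rng(21)).final_state
        nve = rbmd.IntegratorSettings(dt_fs=1.0, quat_tol=1e-12)
        eq = rbmd.run_md(eq, ff, nve, "NVE", n_steps=1000).final_state
        res = rbmd.run_md(eq, ff, nve, "NVE", n_steps=4000)
        t = res.diagnostics["T"].to_numpy()
        # total drift over the window small compared to the fluctuations
        x = np.arange(len(t))
        slope = np.polyfit(x, t, 1)[0]
        assert abs(slope) * len(t) < 1.5 * t.std()
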