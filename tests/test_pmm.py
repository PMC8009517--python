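"""Perturbed matrix method: environment electrostatics, Hamiltonian assembly,
diagonalization, reference-frame selection and collective frames."""

import numpy as np
import pytest

from nanospec.fixio import gen_toy_qc_data
from nanospec.pmm import (
    EnvironmentFrame,
    UnperturbedQCData,
    build_collective_frame,
    build_perturbed_hamiltonian,
    diagonalize_perturbed,
    env_potential_field,
    pmm_pipeline,
    select_reference_frame,
)


def empty_frame():
    return EnvironmentFrame(np.zeros(0), np.zeros((0, 3)))


class TestPotentialField:
    def test_unit_charge_at_unit_distance(self):
        frame = EnvironmentFrame(np.array([1.0]), np.array([[1.0, 0, 0]]))
        v, e = env_potential_field(frame, np.zeros((1, 3)))
        assert np.isclose(v[0], 1.0)
        assert np.isclose(np.linalg.norm(e[0]), 1.0)
        assert np.allclose(e[0], [-1.0, 0, 0])  # field points away from +q

    def test_superposition(self, rng):
        q1 = EnvironmentFrame(np.array([0.7]), np.array([[2.0, 1, 0]]))
        q2 = EnvironmentFrame(np.array([-0.3]), np.array([[0, -3.0, 1]]))
        both = EnvironmentFrame(np.array([0.7, -0.3]),
                                np.vstack([q1.positions, q2.positions]))
        pts = rng.normal(0, 0.5, (5, 3))
        v1, e1 = env_potential_field(q1, pts)
        v2, e2 = env_potential_field(q2, pts)
        vb, eb = env_potential_field(both, pts)
        assert np.allclose(vb, v1 + v2) and np.allclose(eb, e1 + e2)

    def test_ideal_dipole_on_axis_far_field(self):
        d, q = 0.01, 100.0  # p = q·d = 1 au
        frame = EnvironmentFrame(np.array([q, -q]),
                                 np.array([[0, 0, d / 2], [0, 0, -d / 2]]))
        for r in [20.0, 50.0, 100.0]:
            _, e = env_potential_field(frame, np.array([[0, 0, r]]))
            assert np.isclose(np.linalg.norm(e[0]), 2.0 / r**3, rtol=1e-3)

    def test_coincident_charge_raises(self):
        frame = EnvironmentFrame(np.array([1.0]), np.zeros((1, 3)))
        with pytest.raises(ValueError):
            env_potential_field(frame, np.zeros((1, 3)))


class TestHamiltonian:
    def test_empty_environment_is_diagonal_unperturbed(self):
        qc = gen_toy_qc_data(6, 5, seed=1)
        h = build_perturbed_hamiltonian(qc, empty_frame(), "atom")
        assert np.allclose(h, np.diag(qc.energies))

    def test_two_state_single_charge_matches_hand_formula(self):
        energies = np.array([0.0, 0.2])
        dip = np.zeros((2, 2, 3))
        dip[0, 0] = [0.5, 0, 0]
        dip[1, 1] = [-0.2, 0, 0]
        dip[0, 1] = dip[1, 0] = [0.3, 0.1, 0]
        charges = np.array([[0.1, -0.1], [0.25, -0.25]])
        pos = np.array([[0.5, 0, 0], [-0.5, 0, 0]])
        qc = UnperturbedQCData(energies, dip, charges, pos,
                               expansion_center=np.zeros(3))
        s, R = 0.8, np.array([10.0, 0, 0])
        frame = EnvironmentFrame(np.array([s]), R[None])

        # hand evaluation of every element
        v_a = s / np.abs(np.array([9.5, 10.5]))
        e_c = s * (np.zeros(3) - R) / np.linalg.norm(R) ** 3
        h = build_perturbed_hamiltonian(qc, frame, "atom")
        assert np.isclose(h[0, 0], 0.0 + charges[0] @ v_a)
        assert np.isclose(h[1, 1], 0.2 + charges[1] @ v_a)
        assert np.isclose(h[0, 1], -e_c @ dip[0, 1])
        assert h[0, 1] == h[1, 0]

        h2 = build_perturbed_hamiltonian(qc, frame, "qc-center")
        v_c = s / np.linalg.norm(R)
        assert np.isclose(h2[0, 0], 0.0 - e_c @ dip[0, 0] + 0.0 * v_c)
        assert np.isclose(h2[1, 1], 0.2 - e_c @ dip[1, 1] + 0.0 * v_c)

    def test_symmetric_for_random_inputs(self, rng):
        qc = gen_toy_qc_data(7, 6, seed=2)
        frame = EnvironmentFrame(rng.normal(0, 0.2, 30),
                                 rng.normal(0, 20.0, (30, 3)))
        h = build_perturbed_hamiltonian(qc, frame, "atom")
        assert np.array_equal(h, h.T)


class TestDiagonalization:
    def test_zero_perturbation_identity(self):
        qc = gen_toy_qc_data(8, 5, seed=3)
        ps = diagonalize_perturbed(np.diag(qc.energies), qc)
        assert np.allclose(ps.energies, qc.energies)
        assert np.allclose(ps.transition_dipoles, qc.dipoles[0])

    def test_two_by_two_closed_form(self):
        qc = gen_toy_qc_data(2, 3, seed=4)
        h = np.array([[0.05, 0.02], [0.02, 0.21]])
        ps = diagonalize_perturbed(h, qc)
        mean = (h[0, 0] + h[1, 1]) / 2
        split = np.sqrt((h[0, 0] - h[1, 1]) ** 2 / 4 + h[0, 1] ** 2)
        assert np.allclose(ps.energies, [mean - split, mean + split])

    def test_trace_conserved(self, rng):
        qc = gen_toy_qc_data(9, 4, seed=5)
        h = rng.normal(size=(9, 9))
        h = (h + h.T) / 2
        ps = diagonalize_perturbed(h, qc)
        assert np.isclose(ps.energies.sum(), np.trace(h), atol=1e-10)
        assert np.allclose(ps.eigenvectors.T @ ps.eigenvectors, np.eye(9), atol=1e-10)

    def test_first_order_limit_for_distant_weak_charge(self):
        qc = gen_toy_qc_data(5, 4, seed=6)
        frame = EnvironmentFrame(np.array([1e-3]), np.array([[90.0, 10.0, -20.0]]))
        h = build_perturbed_hamiltonian(qc, frame, "atom")
        ps = diagonalize_perturbed(h, qc)
        v_a, _ = env_potential_field(frame, qc.atom_positions)
        first_order = qc.energies + qc.charges @ v_a
        pert = np.abs(h - np.diag(np.diag(h))).max()
        gap = np.diff(qc.energies).min()
        assert np.abs(np.sort(first_order) - ps.energies).max() < 10 * pert**2 / gap

    def test_neutral_environment_at_infinity_recovers_unperturbed(self):
        qc = gen_toy_qc_data(6, 4, seed=7)
        frame = EnvironmentFrame(np.array([0.4, -0.4]),
                                 np.array([[1e8, 0, 0], [-1e8, 0, 0]]))
        h = build_perturbed_hamiltonian(qc, frame, "atom")
        ps = diagonalize_perturbed(h, qc)
        assert np.abs(ps.energies - qc.energies).max() < 1e-12

    def test_energies_continuous_under_small_displacement(self):
        qc = gen_toy_qc_data(6, 4, seed=8)
        base = np.array([[30.0, 5.0, 0.0]])
        e0 = diagonalize_perturbed(
            build_perturbed_hamiltonian(qc, EnvironmentFrame(np.array([0.3]), base)),
            qc,
        ).energies
        e1 = diagonalize_perturbed(
            build_perturbed_hamiltonian(
                qc, EnvironmentFrame(np.array([0.3]), base + 1e-7)
            ),
            qc,
        ).energies
        assert np.abs(e1 - e0).max() < 1e-8


class TestReferenceAndCollective:
    def test_single_frame_selected(self):
        assert select_reference_frame(np.array([[0.1, 0.2, 0.3]])) == 0

    def test_constant_series_ties_to_first(self):
        fields = np.tile([0.5, -0.5, 0.0], (7, 1))
        assert select_reference_frame(fields) == 0

    def test_frame_exactly_at_mean_wins(self):
        fields = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0.0, 0, 0], [0.5, 0.5, 0]])
        mean = fields.mean(axis=0)
        fields[2] = mean
        assert select_reference_frame(fields) == 2

    def test_collective_frame_potential_is_snapshot_mean(self, rng):
        frames = [
            EnvironmentFrame(rng.normal(0, 0.3, 4), rng.normal(0, 15.0, (4, 3)))
            for _ in range(5)
        ]
        coll = build_collective_frame(frames)
        pts = rng.normal(0, 1.0, (3, 3))
        v_coll, _ = env_potential_field(coll, pts)
        v_mean = np.mean([env_potential_field(f, pts)[0] for f in frames], axis=0)
        assert np.allclose(v_coll, v_mean)
        assert np.isclose(coll.charges.sum(),
                          np.mean([f.charges.sum() for f in frames]))

    def test_single_frame_collective_unchanged(self):
        f = EnvironmentFrame(np.array([0.2, -0.2]), np.array([[5.0, 0, 0], [0, 5.0, 0]]))
        coll = build_collective_frame([f])
        assert np.allclose(coll.charges, f.charges)

    def test_empty_collective_raises(self):
        with pytest.raises(ValueError):
            build_collective_frame([])


class TestPipeline:
    def test_single_cluster_single_frame_reduces_to_diagonalization(self):
        qc = gen_toy_qc_data(5, 4, seed=9)
        frame = EnvironmentFrame(np.array([0.2]), np.array([[25.0, 0, 0]]))
        out = pmm_pipeline({0: qc}, [frame], np.array([0]))
        direct = diagonalize_perturbed(build_perturbed_hamiltonian(qc, frame), qc)
        assert np.allclose(out[0][0].energies, direct.energies)

    def test_identical_frames_have_zero_spread(self):
        qc = gen_toy_qc_data(4, 3, seed=10)
        frame = EnvironmentFrame(np.array([0.1]), np.array([[40.0, 0, 0]]))
        out = pmm_pipeline({0: qc}, [frame] * 6, np.zeros(6, int))
        e1 = np.array([ps.excitation_energies for ps in out[0]])
        assert np.ptp(e1, axis=0).max() == 0.0

    def test_weak_fluctuations_center_on_reference(self, rng):
        qc = gen_toy_qc_data(5, 4, seed=11)
        base = np.array([[60.0, 0, 0], [0, 60.0, 0]])
        frames = [
            EnvironmentFrame(np.array([0.3, -0.3]), base + rng.normal(0, 0.5, (2, 3)))
            for _ in range(200)
        ]
        ref = diagonalize_perturbed(
            build_perturbed_hamiltonian(qc, EnvironmentFrame(np.array([0.3, -0.3]), base)),
            qc,
        )
        out = pmm_pipeline({0: qc}, frames, np.zeros(200, int))
        de = np.array([ps.excitation_energies[0] for ps in out[0]])
        se = de.std() / np.sqrt(len(de))
        assert abs(de.mean() - ref.excitation_energies[0]) < 5 * se + 1e-9

    def test_unassigned_cluster_raises(self):
        qc = gen_toy_qc_data(3, 2, seed=12)
        frame = EnvironmentFrame(np.array([0.1]), np.array([[30.0, 0, 0]]))
        with pytest.raises(ValueError, match="without QC data"):
            pmm_pipeline({0: qc}, [frame], np.array([1]))


class TestQCDataValidation:
    def test_asymmetric_dipoles_rejected(self):
        qc = gen_toy_qc_data(3, 2, seed=13)
        bad = qc.dipoles.copy()
        bad[0, 1, 0] += 1.0
        with pytest.raises(ValueError, match="symmetric"):
            UnperturbedQCData(qc.energies, bad, qc.charges, qc.atom_positions)

    def test_inconsistent_net_charge_rejected(self):
        qc = gen_toy_qc_data(3, 2, seed=14)
        bad = qc.charges.copy()
        bad[1, 0] += 0.5
        with pytest.raises(ValueError, match="net charge"):
            UnperturbedQCData(qc.energies, qc.dipoles, bad, qc.atom_positions)

    def test_descending_energies_rejected(self):
        qc = gen_toy_qc_data(3, 2, seed=15)
        with pytest.raises(ValueError, match="ascending"):
            UnperturbedQCData(qc.energies[::-1].copy(), qc.dipoles, qc.charges,
                              qc.atom_positions)
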