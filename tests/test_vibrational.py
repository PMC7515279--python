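"""Local frames, weighted covariances, mode selection and QHO entropy."""

import numpy as np
import pytest

from mccentropy.constants import KB, H_PLANCK, R_GAS, LAMBDA_INTERNAL_TO_SI
from mccentropy.errors import ConfigError, GeometryError, InsufficientDataError, MCCError
from mccentropy.vibrational import (
    CovarianceAccumulator,
    frequencies_from_eigenvalues,
    molecule_weighted_force,
    molecule_weighted_torque,
    principal_frame,
    qho_entropy,
    select_modes,
    ua_weighted_forces,
    ua_weighted_torques,
)


class TestPrincipalFrame:
    def test_single_atom_is_point(self):
        lf = principal_frame(np.array([[1.0, 2.0, 3.0]]), np.array([12.0]))
        np.testing.assert_allclose(lf.origin, [1, 2, 3])
        np.testing.assert_allclose(lf.axes, np.eye(3))
        assert lf.zero_inertia.all()

    def test_dumbbell_closed_form(self):
        coords = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        m = np.array([5.0, 5.0])
        lf = principal_frame(coords, m)
        np.testing.assert_allclose(lf.origin, 0.0, atol=1e-14)
        # transverse inertia 2*m*1^2 on the two leading axes, ~0 on the last
        np.testing.assert_allclose(lf.principal_inertia[:2], 10.0)
        assert lf.zero_inertia[2] and not lf.zero_inertia[:2].any()
        assert abs(abs(lf.axes[2] @ [1, 0, 0]) - 1) < 1e-12

    def test_triangle_matches_characteristic_polynomial(self):
        """Inertia eigenvalues cross-checked via the cubic's roots."""
        coords = np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]])
        m = np.array([15.999, 1.008, 1.008])
        lf = principal_frame(coords, m)
        com = m @ coords / m.sum()
        rel = coords - com
        tensor = (m * (rel**2).sum(1)).sum() * np.eye(3) - np.einsum(
            "a,ai,aj->ij", m, rel, rel
        )
        roots = np.sort(np.roots(np.poly(tensor)).real)[::-1]
        np.testing.assert_allclose(lf.principal_inertia, roots, atol=1e-10)

    def test_coincident_points_rejected(self):
        with pytest.raises(GeometryError):
            principal_frame(np.zeros((3, 3)), np.ones(3))

    def test_axes_right_handed_and_deterministic(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(5, 3))
        m = rng.uniform(1, 16, 5)
        lf1 = principal_frame(coords, m)
        lf2 = principal_frame(coords.copy(), m.copy())
        np.testing.assert_array_equal(lf1.axes, lf2.axes)
        assert np.linalg.det(lf1.axes) == pytest.approx(1.0, abs=1e-12)


class TestWeightedSamples:
    def test_zero_forces_zero_vector(self):
        lf = principal_frame(np.array([[0.0, 0, 0], [1.0, 0, 0]]), np.array([8.0, 8.0]))
        out = molecule_weighted_force(np.zeros((2, 3)), lf, 16.0)
        np.testing.assert_array_equal(out, 0.0)

    def test_halving_and_mass_weighting(self):
        lf = principal_frame(np.array([[1.0, 2, 0], [1.0, 2, 1]]), np.array([8.0, 8.0]))
        lf.axes = np.eye(3)  # identity frame for the closed form
        out = molecule_weighted_force(np.array([[2.0, 0, 0], [0.0, 0, 0]]), lf, 16.0)
        np.testing.assert_allclose(out, [0.25, 0, 0])

    def test_rotation_invariance_of_weighted_components(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        coords = rng.normal(size=(4, 3))
        forces = rng.normal(size=(4, 3))
        m = rng.uniform(1, 16, 4)
        R = Rotation.random(random_state=11).as_matrix()
        lf = principal_frame(coords, m)
        lf_rot = principal_frame(coords @ R.T, m)
        a = molecule_weighted_force(forces, lf, m.sum())
        b = molecule_weighted_force(forces @ R.T, lf_rot, m.sum())
        # axes determinism may flip signs; compare magnitudes per axis
        np.testing.assert_allclose(np.abs(a), np.abs(b), atol=1e-10)

    def test_torque_couple_closed_form(self):
        """±F at ±r on a dumbbell: τ = 2|r||F| about the perpendicular axis."""
        r, f = 2.0, 3.0
        coords = np.array([[r, 0, 0], [-r, 0, 0]])
        forces = np.array([[0, f, 0], [0, -f, 0]])
        lf = principal_frame(coords, np.array([5.0, 5.0]))
        raw_tau = np.cross(coords, forces).sum(axis=0)
        np.testing.assert_allclose(raw_tau, [0, 0, 2 * r * f])
        out = molecule_weighted_torque(coords, forces, lf)
        inertia = 2 * 5.0 * r**2
        np.testing.assert_allclose(
            np.sort(np.abs(out)), [0.0, 2 * r * f / 2 / np.sqrt(inertia)], atol=1e-12
        )

    def test_torque_on_point_body_rejected(self):
        lf = principal_frame(np.array([[0.0, 0, 0]]), np.array([12.0]))
        with pytest.raises(MCCError):
            molecule_weighted_torque(np.zeros((1, 3)), np.zeros((1, 3)), lf)

    def test_single_ua_force_is_unhalved_molecule_force(self, methane):
        lf = principal_frame(
            np.array([[0.0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0.5]]),
            methane.masses,
        )
        forces = np.random.default_rng(0).normal(size=(5, 3))
        ua = ua_weighted_forces(forces, methane, lf)
        mol = molecule_weighted_force(forces, lf, methane.molecular_mass)
        np.testing.assert_allclose(ua, 2 * mol, atol=1e-12)

    def test_point_uas_contribute_no_torques(self, carbon_dioxide):
        coords = np.array([[-1.16, 0, 0], [0, 0, 0], [1.16, 0, 0]])
        forces = np.ones((3, 3))
        out = ua_weighted_torques(coords, forces, carbon_dioxide)
        assert out.size == 0

    def test_bonded_pair_anticorrelation(self, carbon_dioxide):
        """Equal-and-opposite forces on two UAs give off-diagonal = −diagonal."""
        rng = np.random.default_rng(5)
        acc = CovarianceAccumulator(6, level="united-atom", channel="force")
        # use the first two UAs of CO2 (equal-mass O..C ignored; construct directly)
        m = 12.0
        for _ in range(500):
            f = rng.normal(size=3)
            v = np.concatenate([f / np.sqrt(m), -f / np.sqrt(m)])
            acc.add(v)
        cov = acc.finalize()
        np.testing.assert_allclose(cov[:3, 3:], -cov[:3, :3], atol=1e-12)


class TestCovarianceAccumulator:
    def test_constant_vector_gives_outer_product(self):
        c = np.array([1.0, -2.0, 0.5])
        acc = CovarianceAccumulator(3)
        for _ in range(10):
            acc.add(c)
        np.testing.assert_allclose(acc.finalize(), np.outer(c, c), atol=1e-14)

    def test_pooling_is_exact(self):
        """Merging disjoint accumulators is bit-identical to sequential adds."""
        rng = np.random.default_rng(1)
        data = rng.normal(size=(100, 4))
        whole = CovarianceAccumulator(4)
        whole.add_batch(data[:37])
        whole.add_batch(data[37:])
        a = CovarianceAccumulator(4)
        b = CovarianceAccumulator(4)
        a.add_batch(data[:37])
        b.add_batch(data[37:])
        a.merge(b)
        np.testing.assert_array_equal(whole.finalize(), a.finalize())
        one_shot = CovarianceAccumulator(4)
        one_shot.add_batch(data)
        np.testing.assert_allclose(one_shot.finalize(), a.finalize(), rtol=1e-13)

    def test_prescribed_diagonal_covariance(self):
        rng = np.random.default_rng(2)
        var = np.array([4.0, 1.0, 0.25])
        n = 20000
        acc = CovarianceAccumulator(3)
        acc.add_batch(rng.normal(0, np.sqrt(var), size=(n, 3)))
        cov = acc.finalize()
        se = np.sqrt(np.outer(var, var) / n)
        off = ~np.eye(3, dtype=bool)
        assert np.all(np.abs(cov[off]) < 3 * se[off])

    def test_too_few_samples(self):
        acc = CovarianceAccumulator(2)
        acc.add(np.ones(2))
        with pytest.raises(InsufficientDataError):
            acc.finalize()


class TestModeSelection:
    def test_benzene_retains_12_of_18(self, benzene):
        lam = np.linspace(18.0, 1.0, 18)
        spec = select_modes(lam, "united-atom", "force", benzene)
        assert spec.n_vib == 12
        np.testing.assert_allclose(spec.eigenvalues, lam[6:])

    def test_butane_quarters_its_single_dihedral_mode(self, butane):
        lam = np.linspace(12.0, 1.0, 12)
        spec = select_modes(lam, "united-atom", "force", butane)
        assert spec.n_vib == 6
        np.testing.assert_allclose(spec.eigenvalues[-1], lam[-1] / 4.0)
        np.testing.assert_allclose(spec.eigenvalues[:-1], lam[6:-1])
        assert spec.dihedral_softened.sum() == 1

    def test_ethane_linear_retains_one(self, ethane):
        lam = np.linspace(6.0, 1.0, 6)
        spec = select_modes(lam, "united-atom", "force", ethane)
        assert spec.n_vib == 1

    def test_molecule_torque_keeps_rotational_dof(self, ethane, methane):
        spec = select_modes(np.array([3.0, 2.0]), "molecule", "torque", ethane)
        assert spec.n_vib == 2
        spec = select_modes(np.array([3.0, 2.0, 1.0]), "molecule", "torque", methane)
        assert spec.n_vib == 3

    def test_too_few_eigenvalues_rejected(self, benzene):
        with pytest.raises(MCCError):
            select_modes(np.ones(5), "united-atom", "force", benzene)

    def test_near_zero_eigenvalues_excluded(self, ethane):
        lam = np.array([5.0, 4.0, 3.0, 2.0, 1.0, 1e-14])
        spec = select_modes(lam, "united-atom", "force", ethane)
        assert spec.n_vib == 0
        assert spec.n_zero_excluded == 1


class TestFrequencies:
    def test_zero_eigenvalue_zero_frequency(self):
        np.testing.assert_array_equal(
            frequencies_from_eigenvalues(np.array([0.0]), 298.0), [0.0]
        )

    def test_one_terahertz_inversion(self):
        T = 298.0
        lam_si = (2 * np.pi * 1e12) ** 2 * KB * T
        lam_internal = lam_si / LAMBDA_INTERNAL_TO_SI
        nu = frequencies_from_eigenvalues(np.array([lam_internal]), T)
        assert nu[0] == pytest.approx(1e12, rel=1e-12)

    def test_monotone_in_eigenvalue(self):
        lam = np.array([1.0, 2.0, 4.0])
        nu = frequencies_from_eigenvalues(lam, 300.0)
        assert np.all(np.diff(nu) > 0)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ConfigError):
            frequencies_from_eigenvalues(np.array([1.0]), 0.0)

    def test_classical_well_recovers_sqrt_k_over_m(self):
        """⟨F²⟩ = k·kBT for a classical 1D well; ν = (1/2π)√(k/m), no halving."""
        T = 298.0
        k = 50.0  # kJ mol^-1 Å^-2
        m = 15.0  # g mol^-1
        kbt_internal = R_GAS * T / 1000.0  # kJ mol^-1
        rng = np.random.default_rng(99)
        x = rng.normal(0.0, np.sqrt(kbt_internal / k), size=100_000)
        f = -k * x
        lam = np.mean((f / np.sqrt(m)) ** 2)
        nu = frequencies_from_eigenvalues(np.array([lam]), T)[0]
        k_si = k * 1000.0 / 6.02214076e23 / 1e-20
        m_si = m * 1e-3 / 6.02214076e23
        nu_expected = np.sqrt(k_si / m_si) / (2 * np.pi)
        assert nu == pytest.approx(nu_expected, rel=0.02)


class TestQHOEntropy:
    def test_thermal_mode_closed_form(self):
        """A mode at hν = kBT has S = R·(1/(e−1) − ln(1−e⁻¹)) ≈ 8.652."""
        T = 298.0
        nu = KB * T / H_PLANCK
        expected = R_GAS * (1 / (np.e - 1) - np.log(1 - 1 / np.e))
        assert qho_entropy(np.array([nu]), T) == pytest.approx(expected, rel=1e-12)

    def test_high_frequency_limit_is_zero(self):
        assert qho_entropy(np.array([1e18]), 298.0) == pytest.approx(0.0, abs=1e-12)

    def test_additive_over_modes(self):
        T = 250.0
        nu = np.array([3e11, 7e12])
        total = qho_entropy(nu, T)
        parts = qho_entropy(nu[:1], T) + qho_entropy(nu[1:], T)
        assert total == pytest.approx(parts, rel=1e-14)

    def test_decreasing_in_frequency(self):
        T = 298.0
        s = [qho_entropy(np.array([nu]), T) for nu in (1e11, 1e12, 1e13)]
        assert s[0] > s[1] > s[2] >= 0

    def test_zero_frequency_excluded(self):
        T = 298.0
        with_zero = qho_entropy(np.array([0.0, 1e12]), T)
        assert with_zero == pytest.approx(qho_entropy(np.array([1e12]), T))

    def test_negative_frequency_rejected(self):
        with pytest.raises(MCCError):
            qho_entropy(np.array([-1.0]), 298.0)

    def test_stiffer_forces_lower_entropy(self):
        """Scaling all eigenvalues by c² > 1 strictly decreases the entropy."""
        T = 298.0
        lam = np.array([0.5, 1.0, 2.0])
        s1 = qho_entropy(frequencies_from_eigenvalues(lam, T), T)
        s2 = qho_entropy(frequencies_from_eigenvalues(4.0 * lam, T), T)
        assert s2 < s1
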