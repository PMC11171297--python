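import numpy as np
import pytest

from paircc import oopccd, oracles, pccd, properties
from paircc.molecule import Molecule
from paircc.units import DEBYE_PER_AU, au_to_debye


class TestErrorStats:
    def test_identical_lists(self):
        s = properties.error_stats([1.0, 2.0], [1.0, 2.0])
        assert s.mue == s.rmse == 0.0

    def test_symmetric_deviations(self):
        s = properties.error_stats([1.0, -1.0], [0.0, 0.0])
        assert s.mue == 1.0 and s.rmse == 1.0

    def test_uneven_deviations(self):
        s = properties.error_stats([0.0, 2.0], [0.0, 0.0])
        assert s.mue == pytest.approx(1.0)
        assert s.rmse == pytest.approx(np.sqrt(2.0))

    def test_rmse_dominates_mue(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            v = rng.standard_normal(7)
            r = rng.standard_normal(7)
            s = properties.error_stats(v, r)
            assert s.rmse >= s.mue >= 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            properties.error_stats([], [])


class TestTurningPoint:
    def _curve(self, r, mu):
        return properties.DMSCurve(r=np.asarray(r), mu_z=np.asarray(mu),
                                   converged=np.ones(len(r), bool),
                                   method="test")

    def test_parabola_vertex_exact(self):
        r = np.linspace(0.8, 1.8, 11)
        mu = -(r - 1.3123456789) ** 2 + 2.0
        assert properties.turning_point(self._curve(r, mu)) == pytest.approx(
            1.3123456789, abs=1e-10)

    def test_monotone_curve_has_no_interior_turning(self):
        r = np.linspace(0.8, 1.8, 11)
        assert properties.turning_point(self._curve(r, 2.0 * r)) is None

    def test_gaussian_damped_line(self):
        # mu(r) = r exp(-r^2) peaks at 1/sqrt(2)
        r = np.arange(0.3, 1.4, 0.05)
        mu = r * np.exp(-r ** 2)
        tp = properties.turning_point(self._curve(r, mu))
        assert tp == pytest.approx(1 / np.sqrt(2), abs=1e-3)


class TestTotalDipole:
    def test_point_charges_give_one_atomic_unit(self):
        mol = Molecule(["H", "H"], np.array([[0, 0, 0.5], [0, 0, -0.5]]))
        # +1 at +0.5, -1 at -0.5: emulate with nuclear part only
        mu_nuc = mol.nuclear_dipole()  # charges +1, +1
        # difference of shifted pair = unit dipole
        muA = np.einsum("i,ix->x", np.array([1.0, -1.0]), mol.coords)
        assert au_to_debye(muA[2]) == pytest.approx(DEBYE_PER_AU)

    def test_translation_invariance_neutral(self, lih_sto3g):
        from paircc.scf import rhf_dipole, solve_rhf
        from paircc.integrals.ao import build_from_backend
        mol, ao, scf, _ = lih_sto3g
        mu1 = rhf_dipole(ao, scf, mol)
        shift = np.array([0.7, -0.3, 1.1])
        mol2 = Molecule(mol.elements, mol.coords + shift)
        ao2 = build_from_backend(mol2, "sto-3g")
        scf2 = solve_rhf(ao2, 4)
        mu2 = rhf_dipole(ao2, scf2, mol2)
        np.testing.assert_allclose(mu1, mu2, atol=1e-8)

    def test_hf_molecule_sign_convention(self):
        """H at origin, F on +z: H(+)F(-) polarity must give negative
        mu_z."""
        mol = Molecule.diatomic("H", "F", 0.917)
        st = properties.run_method(mol, "cc-pvdz", "rhf")
        assert st.dipole.mu[2] < -1.0

    def test_components_sum(self):
        mol = Molecule.diatomic("H", "F", 0.917)
        st = properties.run_method(mol, "cc-pvdz", "rhf")
        np.testing.assert_allclose(
            st.dipole.mu, st.dipole.nuclear_part + st.dipole.electronic_part,
            atol=1e-12)


class TestDipoleRoutes:
    def test_ao_and_mo_contraction_agree(self, heh_plus_sto3g):
        mol, ao, scf, mi = heh_plus_sto3g
        res = pccd.solve_pccd(mi, 1)
        res.lam = pccd.solve_pccd_lambda(res.t.t, mi, 1)
        gamma = pccd.pccd_response_1rdm(res.t.t, res.lam)
        mu_mo = properties.electronic_dipole_mo(gamma, mi.dipole, np.zeros(3))
        mu_ao = properties.electronic_dipole_ao(gamma, scf.mocoeffs.C, None,
                                                ao.dipole_ints)
        np.testing.assert_allclose(mu_mo, mu_ao, atol=1e-10)

    def test_homonuclear_dipole_zero(self, h2_sto3g):
        mol, _, _, _ = h2_sto3g
        for method in ("rhf", "pccd", "oo-pccd", "pccd-lccsd"):
            st = properties.run_method(mol, "sto-3g", method)
            assert abs(st.dipole.mu[2]) < 1e-8

    def test_heh_plus_oopccd_matches_fci_dipole(self, heh_plus_sto3g):
        """Charged two-electron system: oo-pCCD density reproduces the FCI
        dipole about the same origin."""
        mol, ao, scf, mi = heh_plus_sto3g
        oo = oopccd.solve_oopccd(mi, 1, tol_grad=1e-8)
        gamma = oopccd.relaxed_reference_rdm(oo)
        mu = properties.electronic_dipole_mo(gamma, oo.moints.dipole,
                                             np.zeros(3))
        fci = oracles.dense_fci(mi, 2)
        mu_fci = -fci.electronic_dipole(mi.dipole)
        assert au_to_debye(abs(mu[2] - mu_fci[2])) < 1e-5


class TestFiniteFieldRHF:
    def test_rhf_finite_field_matches_analytic(self, lih_sto3g):
        from paircc.scf import rhf_dipole
        mol, ao, scf, _ = lih_sto3g
        mu_an = au_to_debye(rhf_dipole(ao, scf, mol))
        mu_ff = properties.finite_field_dipole(mol, "sto-3g", "rhf",
                                               freeze=0)
        assert mu_ff[2] == pytest.approx(mu_an[2], abs=1e-6)


class TestScan:
    def test_h2_scan_is_identically_zero(self):
        grid = np.array([0.6, 0.75, 0.9])
        curve = properties.scan_dms("H", "H", grid, "pccd", "sto-3g",
                                    freeze=0, store="dense")
        assert curve.converged.all()
        np.testing.assert_allclose(curve.mu_z, 0.0, atol=1e-8)
        assert properties.turning_point(curve) is None

    def test_atom_order_flips_sign(self):
        grid = np.array([0.85, 0.92, 1.0])
        c1 = properties.scan_dms("H", "F", grid, "pccd", "sto-3g",
                                 store="dense")
        c2 = properties.scan_dms("F", "H", grid, "pccd", "sto-3g",
                                 store="dense")
        np.testing.assert_allclose(c1.mu_z, -c2.mu_z, atol=1e-7)

    def test_failed_points_flagged_not_interpolated(self):
        curve = properties.DMSCurve(
            r=np.array([1.0, 1.1, 1.2]), mu_z=np.array([0.1, np.nan, 0.2]),
            converged=np.array([True, False, True]), method="x")
        assert properties.turning_point(curve) is None  # only 2 good points
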