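import numpy as np
import pytest
import scipy.linalg

from paircc import oopccd, oracles, pccd
from paircc.integrals.ao import build_from_backend
from paircc.mo import transform_to_mo
from paircc.molecule import Molecule
from paircc.scf import solve_rhf
from tests.conftest import random_moints


class TestGradientAndHessian:
    def test_gradient_matches_finite_difference(self):
        mi = random_moints(4, 5)
        res = pccd.solve_pccd(mi, 2, tol=1e-12)
        lam = pccd.solve_pccd_lambda(res.t.t, mi, 2)
        rdms = pccd.pccd_response_rdms(res.t.t, lam)
        g = oopccd.orbital_gradient(mi, rdms)
        h = 1e-5
        for (p, q) in [(0, 1), (0, 3), (1, 2), (2, 3)]:
            k = np.zeros((4, 4))
            k[p, q], k[q, p] = h, -h
            Ep = pccd.solve_pccd(mi.rotate(scipy.linalg.expm(k)), 2,
                                 guess=res.t.t, tol=1e-12).energy
            Em = pccd.solve_pccd(mi.rotate(scipy.linalg.expm(-k)), 2,
                                 guess=res.t.t, tol=1e-12).energy
            assert g[p, q] == pytest.approx((Ep - Em) / (2 * h), abs=1e-6)

    def test_hf_density_gives_brillouin_gradient(self, lih_sto3g):
        """With the reference (HF) densities the occupied-virtual gradient
        block is the Brillouin expression 8*F_ov -- zero at SCF
        convergence."""
        _, _, scf, mi = lih_sto3g
        o = 2
        t0 = np.zeros((o, mi.n - o))
        lam0 = pccd.PairLambda(lam=t0.T.copy())
        rdms = pccd.pccd_response_rdms(t0, lam0)
        g = oopccd.orbital_gradient(mi, rdms)
        F = mi.fock(o)
        np.testing.assert_allclose(g[:o, o:], -4.0 * F[:o, o:], atol=1e-10)
        assert np.abs(g[:o, o:]).max() < 1e-6   # Brillouin at convergence

    def test_diagonal_hessian_matches_finite_difference(self):
        mi = random_moints(5, 5)
        res = pccd.solve_pccd(mi, 2, tol=1e-12)
        lam = pccd.solve_pccd_lambda(res.t.t, mi, 2)
        rdms = pccd.pccd_response_rdms(res.t.t, lam)
        H = oopccd.diagonal_orbital_hessian(mi, rdms)
        h = 1e-4
        for (u, v) in [(0, 1), (0, 4), (2, 3), (1, 2)]:
            def efix(th):
                k = np.zeros((5, 5))
                k[u, v], k[v, u] = th, -th
                mir = mi.rotate(scipy.linalg.expm(k))
                return pccd.rdm_energy(rdms, pccd.PairBlocks(mir, 2))
            fd = (efix(h) - 2 * efix(0.0) + efix(-h)) / h ** 2
            assert H[u, v] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_dexp_adjoint_fd(self):
        mi = random_moints(4, 7)
        rng = np.random.default_rng(2)
        k0 = rng.standard_normal((4, 4)) * 0.3
        k0 = k0 - k0.T
        mir = mi.rotate(scipy.linalg.expm(k0))
        res = pccd.solve_pccd(mir, 2, tol=1e-13)
        lam = pccd.solve_pccd_lambda(res.t.t, mir, 2)
        g_rot = oopccd.orbital_gradient(
            mir, pccd.pccd_response_rdms(res.t.t, lam))
        g = oopccd._dexp_adjoint(k0, g_rot)
        h = 1e-6
        for (p, q) in [(0, 1), (1, 3)]:
            d = np.zeros((4, 4))
            d[p, q], d[q, p] = h, -h
            ep = pccd.solve_pccd(mi.rotate(scipy.linalg.expm(k0 + d)), 2,
                                 tol=1e-13).energy
            em = pccd.solve_pccd(mi.rotate(scipy.linalg.expm(k0 - d)), 2,
                                 tol=1e-13).energy
            assert g[p, q] == pytest.approx((ep - em) / (2 * h), abs=1e-6)


class TestSolver:
    def test_h2_631g_style_equals_fci(self):
        """Two-electron singlet: oo-pCCD is exact in its natural orbitals."""
        mol = Molecule.diatomic("H", "H", 0.74)
        ao = build_from_backend(mol, "cc-pvdz")
        scf = solve_rhf(ao, 2)
        mi = transform_to_mo(ao, scf.mocoeffs.C)
        oo = oopccd.solve_oopccd(mi, 1, tol_grad=1e-7)
        fci = oracles.dense_fci(mi, 2)
        assert oo.energy == pytest.approx(fci.energy, abs=1e-7)

    def test_already_optimal_orbitals_fixed_point(self):
        mol = Molecule.diatomic("H", "H", 0.9)
        ao = build_from_backend(mol, "sto-3g")
        scf = solve_rhf(ao, 2)
        mi = transform_to_mo(ao, scf.mocoeffs.C)
        oo = oopccd.solve_oopccd(mi, 1)
        oo2 = oopccd.solve_oopccd(oo.moints, 1, guess_t=oo.pccd.t.t)
        assert oo2.energy == pytest.approx(oo.energy, abs=1e-10)
        np.testing.assert_allclose(oo2.U, np.eye(2), atol=1e-5)

    def test_lih_below_canonical_pccd(self, lih_sto3g):
        _, _, _, mi = lih_sto3g
        can = pccd.solve_pccd(mi, 2)
        oo = oopccd.solve_oopccd(mi, 2)
        assert oo.energy < can.energy - 1e-4
        assert oo.orbital_gradient_norm < 3e-5

    def test_relaxed_rdm_refuses_unconverged(self, lih_sto3g):
        _, _, _, mi = lih_sto3g
        oo = oopccd.solve_oopccd(mi, 2)
        oo.converged = False
        with pytest.raises(ValueError):
            oopccd.relaxed_reference_rdm(oo)
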