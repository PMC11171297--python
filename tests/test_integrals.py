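import numpy as np
import pytest

from paircc import oracles
from paircc.integrals import ao as aomod
from paircc.integrals import basis as basmod
from paircc.integrals import engine
from paircc.mo import transform_to_mo
from paircc.molecule import Molecule
from paircc.scf import solve_rhf


def quadrature_pair(sh1, sh2, origin=np.zeros(3)):
    """Numerical overlap and dipole blocks for two shells on a cubic grid
    (independent of the Hermite-recursion machinery)."""
    lo, hi, nstep = -7.0, 7.0, 141
    xs = np.linspace(lo, hi, nstep)
    w = (xs[1] - xs[0]) ** 3
    X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
    pts = np.stack([X, Y, Z], -1).reshape(-1, 3)

    def values(sh):
        d = pts - sh.center
        r2 = (d ** 2).sum(1)
        rad = np.zeros(len(pts))
        for a, c in zip(sh.exps, sh.coefs):
            rad += c * np.exp(-a * r2)
        carts = np.array([d[:, 0] ** i * d[:, 1] ** j * d[:, 2] ** k
                          for (i, j, k) in
                          basmod.cartesian_components(sh.l)])
        return basmod.C2S[sh.l] @ (carts * rad)

    v1, v2 = values(sh1), values(sh2)
    S = w * v1 @ v2.T
    D = np.array([w * (v1 * (pts[:, x] - origin[x])) @ v2.T
                  for x in range(3)])
    return S, D


class TestEngineBasics:
    def test_contracted_functions_normalized(self):
        mol = Molecule.diatomic("H", "F", 0.92)
        ao = aomod.build_from_backend(mol, "cc-pvdz")
        np.testing.assert_allclose(np.diag(ao.overlap), 1.0, atol=5e-7)

    def test_overlap_spd_and_symmetries(self):
        mol = Molecule.diatomic("Li", "H", 1.6)
        ao = aomod.build_from_backend(mol, "cc-pvdz")
        w = np.linalg.eigvalsh(ao.overlap)
        assert w.min() > 0
        for M in (ao.overlap, ao.kinetic, ao.nuclear, *ao.dipole_ints):
            np.testing.assert_allclose(M, M.T, atol=1e-12)
        eri = ao.eri
        for perm in ((1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)):
            np.testing.assert_allclose(eri, eri.transpose(perm), atol=1e-12)

    @pytest.mark.parametrize("l1,l2", [(0, 2), (1, 2), (2, 3)])
    def test_overlap_dipole_vs_quadrature(self, l1, l2):
        """High-angular-momentum one-electron integrals against brute-force
        grid integration."""
        sh1 = basmod.make_shell(l1, [0.1, -0.2, 0.3], [1.1, 0.4],
                                [0.7, 0.5])
        sh2 = basmod.make_shell(l2, [-0.4, 0.5, -0.1], [0.9, 0.3],
                                [0.6, 0.6])
        Sc, Tc, Vc, Dc = engine.one_electron_pair(
            sh1.l, sh2.l, sh1.center, sh2.center, sh1.exps, sh1.coefs,
            sh2.exps, sh2.coefs, np.zeros(0), np.zeros((0, 3)),
            np.zeros(3), engine._CARTS)
        T1, T2 = basmod.C2S[l1], basmod.C2S[l2]
        S = T1 @ Sc @ T2.T
        D = np.einsum("xab,pa,qb->xpq", Dc, T1, T2)
        Sq, Dq = quadrature_pair(sh1, sh2)
        np.testing.assert_allclose(S, Sq, atol=2e-5)
        np.testing.assert_allclose(D, Dq, atol=5e-5)

    def test_ss_eri_closed_form(self):
        A = np.zeros(3)
        e, c = np.array([0.8]), np.array([1.0])
        blk = engine.eri_quartet(0, 0, 0, 0, A, A, A, A, e, c, e, c, e, c,
                                 e, c, engine._CARTS)
        p = q = 1.6
        assert blk[0, 0, 0, 0] == pytest.approx(
            2 * np.pi ** 2.5 / (p * q * np.sqrt(p + q)), rel=1e-12)

    def test_rotational_invariance_with_d_functions(self):
        """Total SCF energy of HF/cc-pVDZ is invariant when the molecule is
        rigidly rotated (exercises all d-function integral classes)."""
        r = 0.92
        e1 = solve_rhf(aomod.build_from_backend(
            Molecule.diatomic("H", "F", r), "cc-pvdz"), 10).E_total
        c, s = np.cos(0.7), np.sin(0.7)
        R = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
        coords = np.array([[0, 0, 0], [0, 0, r / 0.52917721092]]) @ R.T
        e2 = solve_rhf(aomod.build_from_backend(
            Molecule(["H", "F"], coords), "cc-pvdz"), 10).E_total
        assert e2 == pytest.approx(e1, abs=1e-9)

    def test_cross_overlap_reduces_to_overlap(self, lih_sto3g):
        """<chi_a|chi_b> between two shell sets equals the ordinary overlap
        when both sets coincide."""
        _, ao, _, _ = lih_sto3g
        T = aomod.cross_overlap(ao.shells, ao.shells)
        np.testing.assert_allclose(T, ao.overlap, atol=1e-13)

    def test_h2_sto3g_textbook_energy(self, h2_sto3g):
        _, ao, scf, _ = h2_sto3g
        assert ao.n_basis == 2
        assert abs(ao.overlap[0, 1]) == pytest.approx(0.6593, abs=2e-4)
        assert scf.E_total == pytest.approx(-1.116714, abs=2e-5)


class TestCholesky:
    def test_exact_low_rank_recovery(self):
        rng = np.random.default_rng(0)
        n, k = 6, 3
        L = rng.standard_normal((k, n, n))
        L = (L + L.transpose(0, 2, 1)) / 2
        eri = np.einsum("Ppq,Prs->pqrs", L, L)
        fac = aomod.cholesky_decompose(eri, 1e-10)
        assert fac.rank == k
        np.testing.assert_allclose(
            np.einsum("Ppq,Prs->pqrs", fac.vectors, fac.vectors), eri,
            atol=1e-9)

    def test_threshold_above_diagonal_gives_rank_zero(self):
        eri = np.full((2, 2, 2, 2), 0.0)
        eri[0, 0, 0, 0] = 1e-7
        fac = aomod.cholesky_decompose(eri, 1e-5)
        assert fac.rank == 0

    def test_reconstruction_error_below_threshold(self, lih_sto3g):
        _, ao, _, _ = lih_sto3g
        for tau in (1e-3, 1e-5, 1e-7):
            fac = aomod.cholesky_decompose(ao.eri, tau)
            rec = np.einsum("Ppq,Prs->pqrs", fac.vectors, fac.vectors)
            n = ao.n_basis
            diag_err = np.abs((ao.eri - rec).reshape(n * n, n * n).diagonal())
            assert diag_err.max() <= tau * (1 + 1e-10)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            aomod.cholesky_decompose(np.zeros((1, 1, 1, 1)), -1.0)


class TestTransforms:
    def test_identity_transform(self, h2_sto3g):
        _, ao, _, _ = h2_sto3g
        mi = transform_to_mo(ao, np.eye(2))
        np.testing.assert_allclose(mi.h, ao.core_hamiltonian, atol=1e-13)
        np.testing.assert_allclose(mi.eri, ao.eri, atol=1e-13)

    def test_cholesky_path_matches_dense(self, lih_sto3g):
        _, ao, scf, mi_dense = lih_sto3g
        tau = 1e-7
        ao2 = aomod.AOIntegralSet(**{**ao.__dict__})
        ao2.eri = None
        ao2.chol = aomod.cholesky_decompose(ao.eri, tau)
        mi_chol = transform_to_mo(ao2, scf.mocoeffs.C)
        np.testing.assert_allclose(mi_chol.eri_dense(), mi_dense.eri,
                                   atol=5e-6)

    def test_frozen_core_matches_constrained_fci(self, lih_sto3g):
        """Folding the Li 1s equals the core-constrained full calculation."""
        from paircc.mo import fold_frozen_core
        _, _, _, mi = lih_sto3g
        mif = fold_frozen_core(mi, [0])
        e_act = oracles.dense_fci(mif, 2).energy
        e_con = oracles.dense_fci(mi, 4, core=(0,)).energy
        assert e_act == pytest.approx(e_con, abs=1e-8)

    def test_empty_frozen_set_identity(self, h2_sto3g):
        from paircc.mo import fold_frozen_core
        _, _, _, mi = h2_sto3g
        assert fold_frozen_core(mi, []) is mi


class TestEmbedding:
    def test_zero_potential_identity(self, h2_sto3g):
        _, ao, scf, _ = h2_sto3g
        ao2 = aomod.add_embedding_potential(ao, np.zeros((2, 2)))
        assert solve_rhf(ao2, 2).E_total == pytest.approx(scf.E_total,
                                                          abs=1e-12)

    def test_overlap_shift_gauge_identity(self, lih_sto3g):
        """v = eps*S shifts the energy by eps*N_elec, dipole unchanged."""
        from paircc.scf import rhf_dipole
        mol, ao, scf, _ = lih_sto3g
        eps = 0.037
        ao2 = aomod.add_embedding_potential(ao, eps * ao.overlap)
        scf2 = solve_rhf(ao2, 4)
        assert scf2.E_total - scf.E_total == pytest.approx(4 * eps, abs=1e-8)
        np.testing.assert_allclose(rhf_dipole(ao2, scf2, mol),
                                   rhf_dipole(ao, scf, mol), atol=1e-7)

    def test_asymmetric_rejected(self, h2_sto3g):
        _, ao, _, _ = h2_sto3g
        v = np.array([[0.0, 0.1], [0.0, 0.0]])
        with pytest.raises(ValueError):
            aomod.add_embedding_potential(ao, v)
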