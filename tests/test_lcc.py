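import numpy as np
import pytest

from paircc import oracles, pccd
from paircc.lcc import (LCCWorkspace, combine_rdm, lcc_correlation_1rdm,
                        solve_lcc, solve_lcc_lambda)
from paircc.lcc import derive, engine, so_terms, spinsum
from paircc.mo import MOIntegralSet
from tests.conftest import random_moints


@pytest.fixture(scope="module")
def small_system():
    mi = random_moints(5, 9)
    res = pccd.solve_pccd(mi, 2)
    return mi, 2, res.t.t


class TestTermList:
    def test_coefficients_rederive_from_oracle(self):
        """A fresh least-squares fit against the determinant-space residual
        reproduces the frozen rational coefficients exactly."""
        s, d = derive.fit_coefficients(instances=((4, 2, 0), (5, 2, 1)))
        assert s == so_terms.SINGLES_COEFFS
        assert d == so_terms.DOUBLES_COEFFS

    def test_spatial_equals_spin_orbital_on_random_amplitudes(self):
        """The generated closed-shell terms match the spin-orbital list for
        singlet-embedded amplitudes (exercises every contraction)."""
        n, o = 5, 2
        v = n - o
        mi = random_moints(n, 42)
        f_so, v_so, _ = oracles.spinorb_tensors(mi, o)
        no, nv = 2 * o, 2 * v
        rng = np.random.default_rng(1)
        t1 = rng.standard_normal((o, v)) * 0.2
        t2 = rng.standard_normal((o, o, v, v)) * 0.2
        t2 = (t2 + t2.transpose(1, 0, 3, 2)) / 2
        t1_so = np.zeros((no, nv))
        t1_so[:o, :v] = t1_so[o:, v:] = t1
        t2_so = np.zeros((no, no, nv, nv))
        so = np.array([0] * o + [1] * o)
        sv = np.array([0] * v + [1] * v)
        for I in range(no):
            for J in range(no):
                for A in range(nv):
                    for B in range(nv):
                        val = 0.0
                        if so[I] == sv[A] and so[J] == sv[B]:
                            val += t2[I % o, J % o, A % v, B % v]
                        if so[I] == sv[B] and so[J] == sv[A]:
                            val -= t2[I % o, J % o, B % v, A % v]
                        t2_so[I, J, A, B] = val
        st_so = engine.TensorStore(no, nv, full={"f": f_so, "v": v_so},
                                   plain={"t1": t1_so, "t2": t2_so})
        R1_so = engine.evaluate(so_terms.singles_terms(), st_so, (no, nv))
        R2_so = engine.evaluate(so_terms.doubles_terms(), st_so,
                                (no, no, nv, nv))
        st_sp = engine.TensorStore(o, v, full={"f": mi.fock(o),
                                               "w": mi.eri_dense()},
                                   plain={"t1": t1, "t2": t2})
        R1_sp = engine.evaluate(spinsum.R1_TERMS, st_sp, (o, v))
        R2_sp = engine.evaluate(spinsum.R2_TERMS, st_sp, (o, o, v, v))
        np.testing.assert_allclose(R1_sp, R1_so[:o, :v], atol=1e-12)
        np.testing.assert_allclose(R2_sp, R2_so[:o, o:, :v, v:], atol=1e-12)


class TestSolver:
    @pytest.mark.parametrize("variant", ["lccd", "lccsd"])
    def test_converged_amplitudes_satisfy_determinant_equations(
            self, small_system, variant):
        mi, o, tp = small_system
        lr = solve_lcc(tp, mi, o, variant)
        space = oracles.DeterminantSpace(mi.n, 2 * o, "all")
        Tpr = oracles.build_tprime(space, o, lr.amps.t1, lr.amps.t2)
        man, rvec, _, sp = oracles.lcc_residual_vector(mi, o, tp, Tpr)
        ranks = np.array([sp.rank(i) for i in man])
        keep = np.ones(len(man), bool)
        if variant == "lccd":
            keep = ranks == 2
        assert np.abs(rvec[keep]).max() < 1e-8

    def test_energy_matches_determinant_space(self, small_system):
        mi, o, tp = small_system
        lr = solve_lcc(tp, mi, o, "lccsd")
        space = oracles.DeterminantSpace(mi.n, 2 * o, "all")
        H = oracles.build_dense_hamiltonian(mi, space)
        T = oracles.pair_cluster_matrix(space, tp, o)
        Tpr = oracles.build_tprime(space, o, lr.amps.t1, lr.amps.t2)
        e0 = np.zeros(space.dim)
        e0[space.hf_index()] = 1.0
        w = oracles.apply_exp(-T, H @ oracles.apply_exp(T, Tpr @ e0))
        assert lr.E_lcc == pytest.approx(w[space.hf_index()], abs=1e-10)

    def test_cepa0_limit(self, small_system):
        """With tp = 0 the equations are canonical linearized CCSD; the
        solution satisfies the bare projected equations."""
        mi, o, _ = small_system
        tp0 = np.zeros((o, mi.n - o))
        lr = solve_lcc(tp0, mi, o, "lccsd")
        space = oracles.DeterminantSpace(mi.n, 2 * o, "all")
        Tpr = oracles.build_tprime(space, o, lr.amps.t1, lr.amps.t2)
        _, rvec, _, _ = oracles.lcc_residual_vector(mi, o, tp0, Tpr)
        assert np.abs(rvec).max() < 1e-8

    def test_pair_channel_excluded_everywhere(self, small_system):
        mi, o, tp = small_system
        v = mi.n - o
        lr = solve_lcc(tp, mi, o, "lccsd")
        lam = solve_lcc_lambda(lr, tp, mi, o)
        io, iv = np.arange(o), np.arange(v)
        for t2 in (lr.amps.t2, lam.l2):
            assert np.abs(t2[io[:, None], io[:, None],
                             iv[None, :], iv[None, :]]).max() == 0.0

    def test_residual_is_affine_in_tprime(self, small_system):
        """residual(a T1 + (1-a) T2) = a r(T1) + (1-a) r(T2)."""
        mi, o, tp = small_system
        v = mi.n - o
        ws = LCCWorkspace(mi, o, tp)
        rng = np.random.default_rng(5)

        def rand_amps():
            t1 = rng.standard_normal((o, v))
            t2 = rng.standard_normal((o, o, v, v))
            t2 = ws.zero_pair(ws.symmetrize(t2))
            return t1, t2

        (a1, b1), (a2, b2) = rand_amps(), rand_amps()
        alpha = 0.37
        src1, src2 = ws.source(True)

        def resid(t1, t2):
            j1, j2 = ws.jac_action(t1, t2, True)
            return src1 + j1, src2 + j2

        rA = resid(a1, b1)
        rB = resid(a2, b2)
        rC = resid(alpha * a1 + (1 - alpha) * a2,
                   alpha * b1 + (1 - alpha) * b2)
        for k in range(2):
            np.testing.assert_allclose(
                rC[k], alpha * rA[k] + (1 - alpha) * rB[k], atol=1e-10)

    def test_fragment_additivity(self, h2_sto3g):
        """E_lcc over two noninteracting H2 fragments is twice the
        single-fragment value."""
        _, _, _, mi = h2_sto3g
        res = pccd.solve_pccd(mi, 1)
        one = solve_lcc(res.t.t, mi, 1, "lccsd")
        n = mi.n
        h2x = np.zeros((2 * n, 2 * n))
        eri2 = np.zeros((2 * n,) * 4)
        for off in (0, n):
            sl = slice(off, off + n)
            h2x[sl, sl] = mi.h
            eri2[sl, sl, sl, sl] = mi.eri
        perm = np.array([0, n, 1, n + 1])
        dimer = MOIntegralSet(h=h2x[np.ix_(perm, perm)],
                              eri=eri2[np.ix_(perm, perm, perm, perm)],
                              core_energy=0.0)
        res2 = pccd.solve_pccd(dimer, 2)
        two = solve_lcc(res2.t.t, dimer, 2, "lccsd")
        assert two.E_lcc == pytest.approx(2 * one.E_lcc, abs=1e-9)


class TestDensities:
    @pytest.mark.parametrize("variant", ["lccd", "lccsd"])
    def test_rdm_is_f_derivative_under_freezing_protocol(
            self, small_system, variant):
        """gamma_LCC contracts with a symmetric one-electron perturbation to
        the derivative of E_lcc with orbitals and tp frozen."""
        mi, o, tp = small_system
        lr = solve_lcc(tp, mi, o, variant)
        lam = solve_lcc_lambda(lr, tp, mi, o)
        gam = lcc_correlation_1rdm(lr, lam, tp, mi, o)
        assert abs(np.trace(gam)) < 1e-8
        np.testing.assert_allclose(gam, gam.T, atol=1e-10)
        rng = np.random.default_rng(3)
        delta = rng.standard_normal((mi.n, mi.n))
        delta = (delta + delta.T) / 2
        eps = 1e-6
        es = []
        for s in (eps, -eps):
            mi2 = MOIntegralSet(h=mi.h + s * delta, eri=mi.eri,
                                core_energy=mi.core_energy)
            es.append(solve_lcc(tp, mi2, o, variant, tol=1e-11).E_lcc)
        dE = (es[0] - es[1]) / (2 * eps)
        assert dE == pytest.approx(float((gam * delta).sum()), abs=2e-7)

    def test_zero_correction_zero_density(self, small_system):
        mi, o, tp = small_system
        from paircc.lcc.solver import LCCAmplitudes, LCCLambda, LCCResult
        v = mi.n - o
        z2 = np.zeros((o, o, v, v))
        lr = LCCResult(E_lcc=0.0, amps=LCCAmplitudes(np.zeros((o, v)), z2),
                       lam=None, variant="lccsd", iterations=0)
        lam = LCCLambda(np.zeros((o, v)), z2)
        gam = lcc_correlation_1rdm(lr, lam, tp, mi, o)
        assert np.abs(gam).max() < 1e-14

    def test_combine_rdm(self, small_system):
        mi, o, tp = small_system
        ref = np.diag(np.r_[2.0 * np.ones(o), np.zeros(mi.n - o)])
        assert combine_rdm(ref, np.zeros_like(ref)) is not ref
        np.testing.assert_allclose(combine_rdm(ref, np.zeros_like(ref)), ref)
        with pytest.raises(ValueError):
            combine_rdm(ref, np.zeros((2, 2)))

    def test_h2_combined_density_equals_fci(self, h2_sto3g):
        """pCCD+LCC on H2: combined 1-RDM reproduces the FCI density."""
        _, _, _, mi = h2_sto3g
        res = pccd.solve_pccd(mi, 1)
        res.lam = pccd.solve_pccd_lambda(res.t.t, mi, 1)
        gamma_ref = pccd.pccd_response_1rdm(res.t.t, res.lam)
        lr = solve_lcc(res.t.t, mi, 1, "lccsd")
        lam = solve_lcc_lambda(lr, res.t.t, mi, 1)
        gam = combine_rdm(gamma_ref, lcc_correlation_1rdm(lr, lam, res.t.t,
                                                          mi, 1))
        fci = oracles.dense_fci(mi, 2)
        np.testing.assert_allclose(gam, fci.rdm1, atol=1e-6)
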