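import numpy as np
import pytest

from paircc import oracles, pccd
from paircc.mo import MOIntegralSet
from tests.conftest import random_moints


class TestResidual:
    @pytest.mark.parametrize("n,o,seed", [(4, 2, 1), (5, 2, 2), (6, 3, 3)])
    def test_matches_determinant_projection(self, n, o, seed):
        """The closed-form quadratic residual equals the brute-force
        projection <ia|e^-Tp H e^Tp|0> for random amplitudes."""
        mi = random_moints(n, seed)
        blocks = pccd.PairBlocks(mi, o)
        t = np.random.default_rng(seed).standard_normal((o, n - o)) * 0.25
        R_closed = pccd.pccd_residual(t, blocks)
        R_det = oracles.projected_residual_check(t, mi, o)
        np.testing.assert_allclose(R_closed, R_det, atol=1e-12)

    def test_zero_amplitudes_give_pair_exchange_integral(self):
        mi = random_moints(5, 7)
        blocks = pccd.PairBlocks(mi, 2)
        R0 = pccd.pccd_residual(np.zeros((2, 3)), blocks)
        R_det = oracles.projected_residual_check(np.zeros((2, 3)), mi, 2)
        np.testing.assert_allclose(R0, blocks.Kov, atol=1e-12)
        np.testing.assert_allclose(R0, R_det, atol=1e-12)

    def test_no_two_electron_integrals_no_residual(self):
        mi = MOIntegralSet(h=np.diag([0.0, 1.0, 2.0]),
                           eri=np.zeros((3, 3, 3, 3)))
        blocks = pccd.PairBlocks(mi, 1)
        assert np.all(pccd.pccd_residual(np.zeros((1, 2)), blocks) == 0.0)


class TestSolver:
    def test_h2_equals_fci(self, h2_sto3g):
        _, _, scf, mi = h2_sto3g
        res = pccd.solve_pccd(mi, 1)
        fci = oracles.dense_fci(mi, 2)
        assert res.energy == pytest.approx(fci.energy, abs=1e-9)
        assert res.E_ref == pytest.approx(scf.E_total, abs=1e-10)
        assert res.E_corr < 0

    def test_pairing_model_pt2_limit(self):
        """Weak coupling: amplitudes and energy approach perturbation
        theory, with O(G^3) error in the energy."""
        lev = np.array([0.0, 1.0, 2.2, 3.1])
        devs = []
        for G in (4e-3, 2e-3, 1e-3):
            mi = oracles.make_pairing_hamiltonian(lev, G)
            res = pccd.solve_pccd(mi, 2)
            e2 = -sum(G ** 2 / (2 * (lev[a] - lev[i]))
                      for i in (0, 1) for a in (2, 3))
            devs.append(abs(res.E_corr - e2))
        devs = np.array(devs)
        assert devs[0] / devs[1] == pytest.approx(8.0, rel=0.2)  # ~G^3
        assert devs[1] / devs[2] == pytest.approx(8.0, rel=0.2)

    def test_converged_amplitudes_pass_oracle(self, pairing_2x4):
        res = pccd.solve_pccd(pairing_2x4, 2)
        R = oracles.projected_residual_check(res.t.t, pairing_2x4, 2)
        assert np.abs(R).max() < 1e-8

    def test_size_consistency_two_fragments(self, h2_sto3g):
        """Two noninteracting H2 fragments: E_corr doubles exactly."""
        _, _, _, mi = h2_sto3g
        one = pccd.solve_pccd(mi, 1)
        n = mi.n
        h2x = np.zeros((2 * n, 2 * n))
        eri2 = np.zeros((2 * n,) * 4)
        for off in (0, n):
            sl = slice(off, off + n)
            h2x[sl, sl] = mi.h
            eri2[sl, sl, sl, sl] = mi.eri
        # orbital order: both bonding orbitals first (occupied block)
        order = [0, n, 1, n + 1]
        perm = np.array(order + [])
        h2x = h2x[np.ix_(perm, perm)]
        eri2 = eri2[np.ix_(perm, perm, perm, perm)]
        dimer = MOIntegralSet(h=h2x, core_energy=2 * mi.core_energy,
                              eri=eri2)
        two = pccd.solve_pccd(dimer, 2)
        assert two.E_corr == pytest.approx(2 * one.E_corr, abs=1e-9)


class TestLambdaAndDensities:
    def test_two_electron_rdm_matches_fci(self, h2_sto3g):
        _, _, _, mi = h2_sto3g
        res = pccd.solve_pccd(mi, 1)
        lam = pccd.solve_pccd_lambda(res.t.t, mi, 1)
        gamma = pccd.pccd_response_1rdm(res.t.t, lam)
        fci = oracles.dense_fci(mi, 2)
        np.testing.assert_allclose(gamma, fci.rdm1, atol=1e-7)

    def test_zero_coupling_zero_lambda(self):
        mi = oracles.make_pairing_hamiltonian([0.0, 1.0, 2.0], G=0.0)
        res = pccd.solve_pccd(mi, 1)
        lam = pccd.solve_pccd_lambda(res.t.t, mi, 1)
        assert np.abs(lam.lam).max() < 1e-12

    def test_reference_limit_rdm(self):
        lam = pccd.PairLambda(lam=np.zeros((3, 2)))
        g = pccd.pccd_response_1rdm(np.zeros((2, 3)), lam)
        np.testing.assert_allclose(np.diag(g), [2, 2, 0, 0, 0])
        assert np.abs(g - np.diag(np.diag(g))).max() == 0.0

    def test_trace_and_energy_identity(self, pairing_2x4):
        res = pccd.solve_pccd(pairing_2x4, 2)
        lam = pccd.solve_pccd_lambda(res.t.t, pairing_2x4, 2)
        rdms = pccd.pccd_response_rdms(res.t.t, lam)
        assert np.trace(rdms.rdm1()) == pytest.approx(4.0, abs=1e-10)
        blocks = pccd.PairBlocks(pairing_2x4, 2)
        assert pccd.rdm_energy(rdms, blocks) == pytest.approx(res.energy,
                                                              abs=1e-9)

    def test_2rdm_blocks_match_fci_for_two_electrons(self, h2_sto3g):
        """Pair and number-number blocks vs the exact wave function."""
        _, _, _, mi = h2_sto3g
        res = pccd.solve_pccd(mi, 1)
        lam = pccd.solve_pccd_lambda(res.t.t, mi, 1)
        rdms = pccd.pccd_response_rdms(res.t.t, lam)
        fci = oracles.dense_fci(mi, 2, filter="seniority0")
        space = fci.space
        civ = fci.civec
        for p in range(2):
            for q in range(2):
                if p == q:
                    ref = fci.rdm1[p, p] / 2.0   # <N_p>
                else:
                    P = oracles.pair_excitation_matrix(space, q, p)
                    ref = civ @ (P @ civ)        # move a pair q -> p
                assert rdms.Pi[p, q] == pytest.approx(ref, abs=1e-7)
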