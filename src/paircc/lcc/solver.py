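"""Linearized CC corrections (LCCD / LCCSD) on a pCCD reference.

The equations are <mu| Hbar + [Hbar, T'] |0> = 0 with Hbar = e^-Tp H e^Tp
and T' the singles/doubles correction with the electron-pair channel
excluded (t2'[i,i,a,a] = 0; mixed rows i=j, a!=b and i!=j, a=b stay).
Because [Tp, T'] = 0 they are exactly the linearization of the CC residual
around (t1=0, t2=Tp); the source, the linear map, its transpose (Lambda
equations) and the one-electron response density are all mechanical
operations on one generated term list (``spinsum``).  With Tp = 0 the
equations reduce to canonical linearized CCSD (CEPA(0)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from ..mo import MOIntegralSet
from . import engine, spinsum

VARIANTS = ("lccd", "lccsd")


@dataclass
class LCCAmplitudes:
    t1: np.ndarray | None   # (o, v); None for LCCD
    t2: np.ndarray          # (o, o, v, v), t2[i,j,a,b] = t2[j,i,b,a]


@dataclass
class LCCLambda:
    l1: np.ndarray | None
    l2: np.ndarray


@dataclass
class LCCResult:
    E_lcc: float
    amps: LCCAmplitudes
    lam: LCCLambda | None
    variant: str
    iterations: int
    method: str = "diis"


class LCCWorkspace:
    """Blocks, base (pCCD-dressed) amplitudes, and term-list operations."""

    def __init__(self, moints: MOIntegralSet, n_pairs: int, tp: np.ndarray):
        self.n = moints.n
        self.o = n_pairs
        self.v = self.n - self.o
        self.f = moints.fock(self.o)
        osl = np.arange(self.o)
        vsl = np.arange(self.o, self.n)
        self._moints = moints
        self._slices = {"o": osl, "v": vsl}

        t2_base = np.zeros((self.o, self.o, self.v, self.v))
        io = np.arange(self.o)
        iv = np.arange(self.v)
        t2_base[io[:, None], io[:, None], iv[None, :], iv[None, :]] = tp
        self.t2_base = t2_base
        self.store = engine.TensorStore(
            self.o, self.v, full={"f": self.f},
            blocked={"w": self._w_block},
            plain={"t1": np.zeros((self.o, self.v)), "t2": t2_base})
        # Coulomb/exchange combination driving the energy and Lambda source
        w_ovov = self._w_block("ovov")
        self.L_ovov = (2.0 * np.einsum("iajb->ijab", w_ovov)
                       - np.einsum("ibja->ijab", w_ovov))
        self.f_ov = self.f[np.ix_(osl, vsl)]

    def _w_block(self, classes):
        sl = [self._slices[c] for c in classes]
        return self._moints.block(*sl)

    # -- projections -------------------------------------------------------
    def zero_pair(self, t2):
        io = np.arange(self.o)
        iv = np.arange(self.v)
        t2[io[:, None], io[:, None], iv[None, :], iv[None, :]] = 0.0
        return t2

    def symmetrize(self, t2):
        return 0.5 * (t2 + t2.transpose(1, 0, 3, 2))

    # -- term-list operations ---------------------------------------------
    def source(self, with_singles):
        r2 = engine.evaluate(spinsum.R2_TERMS, self.store,
                             (self.o, self.o, self.v, self.v))
        r2 = self.zero_pair(self.symmetrize(r2))
        r1 = None
        if with_singles:
            r1 = engine.evaluate(spinsum.R1_TERMS, self.store,
                                 (self.o, self.v))
        return r1, r2

    def jac_action(self, d1, d2, with_singles):
        deltas = {"t2": d2}
        if d1 is not None:
            deltas["t1"] = d1
        r2 = engine.jacobian_action(spinsum.R2_TERMS, self.store, deltas,
                                    (self.o, self.o, self.v, self.v))
        r2 = self.zero_pair(self.symmetrize(r2))
        r1 = None
        if with_singles:
            r1 = engine.jacobian_action(spinsum.R1_TERMS, self.store, deltas,
                                        (self.o, self.v))
        return r1, r2

    def transpose_action(self, l1, l2, with_singles):
        """Adjoint of jac_action: returns (g1, g2) with g = A^T lambda."""
        g2 = engine.transpose_action(spinsum.R2_TERMS, self.store, l2, "t2",
                                     (self.o, self.o, self.v, self.v))
        g1 = None
        if with_singles:
            g1 = engine.transpose_action(spinsum.R2_TERMS, self.store, l2,
                                         "t1", (self.o, self.v))
            g1 += engine.transpose_action(spinsum.R1_TERMS, self.store, l1,
                                          "t1", (self.o, self.v))
            g2 += engine.transpose_action(spinsum.R1_TERMS, self.store, l1,
                                          "t2", (self.o, self.o, self.v, self.v))
        g2 = self.zero_pair(self.symmetrize(g2))
        return g1, g2

    # -- scalar pieces -----------------------------------------------------
    def energy(self, amps: LCCAmplitudes) -> float:
        e = float((self.L_ovov * amps.t2).sum())
        if amps.t1 is not None:
            e += 2.0 * float((self.f_ov * amps.t1).sum())
        return e

    def lambda_source(self, with_singles):
        c2 = self.zero_pair(self.L_ovov.copy())
        c1 = 2.0 * self.f_ov if with_singles else None
        return c1, c2

    def denominators(self):
        fd = np.diag(self.f)
        d1 = fd[:self.o, None] - fd[None, self.o:]
        d2 = (fd[:self.o, None, None, None] + fd[None, :self.o, None, None]
              - fd[None, None, self.o:, None] - fd[None, None, None, self.o:])
        for d in (d1, d2):
            small = np.abs(d) < 0.05
            d[small] = np.sign(d[small] + (d[small] == 0)) * 0.05
        return d1, d2


def _pack(d1, d2):
    if d1 is None:
        return d2.ravel().copy()
    return np.concatenate([d1.ravel(), d2.ravel()])


def _unpack(x, o, v, with_singles):
    if not with_singles:
        return None, x.reshape(o, o, v, v)
    n1 = o * v
    return x[:n1].reshape(o, v), x[n1:].reshape(o, o, v, v)


def _solve_linear(apply_A, rhs, precon, tol=1e-8, maxiter=60):
    """DIIS-accelerated preconditioned Richardson; GMRES fallback.

    Solves A x = rhs; ``precon`` multiplies by the approximate inverse
    diagonal.  Residual max-norm < tol on exit.
    """
    from ..pccd import DIIS
    x = precon(rhs)
    diis = DIIS(8)
    it = 0
    for it in range(1, maxiter + 1):
        r = apply_A(x) - rhs
        if np.abs(r).max() < tol:
            return x, it, "diis"
        x = diis.step(x - precon(r), r)
        if not np.isfinite(x).all():
            break
    # GMRES fallback for ill-conditioned (stretched-geometry) systems
    n = rhs.size
    A = spla.LinearOperator((n, n), matvec=apply_A)
    M = spla.LinearOperator((n, n), matvec=precon)
    x, info = spla.gmres(A, rhs, M=M, rtol=1e-12, atol=1e-14,
                         restart=50, maxiter=40)
    r = np.abs(apply_A(x) - rhs).max()
    if r > tol:
        raise RuntimeError(
            f"LCC linear solve failed (DIIS {maxiter} iters, GMRES "
            f"info={info}); residual {r:.2e}")
    return x, it + 40, "gmres"


def solve_lcc(tp: np.ndarray, moints: MOIntegralSet, n_pairs: int,
              variant: str = "lccsd", tol=1e-8, ws: LCCWorkspace | None = None
              ) -> LCCResult:
    """Solve the linear LCC amplitude equations on a converged pCCD
    reference; E_lcc = <0| H T' |0>."""
    variant = variant.lower()
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    ws = ws or LCCWorkspace(moints, n_pairs, tp)
    singles = variant == "lccsd"
    r1, r2 = ws.source(singles)
    rhs = -_pack(r1, r2)
    d1, d2 = ws.denominators()

    def apply_A(x):
        a1, a2 = _unpack(x, ws.o, ws.v, singles)
        if a2 is not None:
            a2 = ws.zero_pair(a2.copy())
        j1, j2 = ws.jac_action(a1, a2, singles)
        return _pack(j1, j2)

    def precon(x):
        a1, a2 = _unpack(x, ws.o, ws.v, singles)
        a2 = a2 / d2
        return _pack(a1 / d1 if a1 is not None else None, a2)

    x, it, method = _solve_linear(apply_A, rhs, precon, tol=tol)
    t1, t2 = _unpack(x, ws.o, ws.v, singles)
    t2 = ws.zero_pair(ws.symmetrize(t2))
    amps = LCCAmplitudes(t1=t1, t2=t2)
    return LCCResult(E_lcc=ws.energy(amps), amps=amps, lam=None,
                     variant=variant, iterations=it, method=method)


def solve_lcc_lambda(result: LCCResult, tp: np.ndarray,
                     moints: MOIntegralSet, n_pairs: int, tol=1e-9,
                     ws: LCCWorkspace | None = None) -> LCCLambda:
    """Adjoint equations A^T lambda = -dE/dT'; linear-truncation Lambda."""
    ws = ws or LCCWorkspace(moints, n_pairs, tp)
    singles = result.variant == "lccsd"
    c1, c2 = ws.lambda_source(singles)
    rhs = -_pack(c1, c2)
    d1, d2 = ws.denominators()

    def apply_AT(x):
        l1, l2 = _unpack(x, ws.o, ws.v, singles)
        if l2 is not None:
            l2 = ws.zero_pair(l2.copy())
        g1, g2 = ws.transpose_action(l1, l2, singles)
        return _pack(g1, g2)

    def precon(x):
        a1, a2 = _unpack(x, ws.o, ws.v, singles)
        a2 = a2 / d2
        return _pack(a1 / d1 if a1 is not None else None, a2)

    x, _, _ = _solve_linear(apply_AT, rhs, precon, tol=tol)
    l1, l2 = _unpack(x, ws.o, ws.v, singles)
    l2 = ws.zero_pair(ws.symmetrize(l2))
    return LCCLambda(l1=l1, l2=l2)


def lcc_correlation_1rdm(result: LCCResult, lam: LCCLambda, tp: np.ndarray,
                         moints: MOIntegralSet, n_pairs: int,
                         ws: LCCWorkspace | None = None) -> np.ndarray:
    """The LCC correlation-only 1-RDM: d(E_lcc Lagrangian)/df at frozen
    orbitals and frozen pair amplitudes.

    gamma = d/df [ <0|H T'|0> + lambda . (source + A T') ].  Orbital
    relaxation due to the LCC correction is not included, and the pair
    Lambda does not couple in: the combined density then differentiates
    E(oo-pCCD) with full relaxation plus E_LCC with orbitals and Tp frozen.
    Traceless by particle-number conservation (checked).
    """
    ws = ws or LCCWorkspace(moints, n_pairs, tp)
    singles = result.variant == "lccsd"
    n = ws.n
    gamma = np.zeros((n, n))
    osl = np.arange(ws.o)
    vsl = np.arange(ws.o, n)
    # dE/df: E = 2 sum f_ia t1_ia (+ t2 part, f-independent)
    if singles:
        gamma[np.ix_(osl, vsl)] += 2.0 * result.amps.t1
    # lambda . d(source)/df at base amplitudes
    lists = [(spinsum.R2_TERMS, lam.l2)]
    if singles:
        lists.append((spinsum.R1_TERMS, lam.l1))
    primes = {"t2": result.amps.t2}
    if singles:
        primes["t1"] = result.amps.t1
    for terms, l in lists:
        gamma += engine.f_gradient(terms, ws.store, l, ws.o, ws.v)
        gamma += engine.f_gradient_linearized(terms, ws.store, l, primes,
                                              ws.o, ws.v)
    gamma = 0.5 * (gamma + gamma.T)
    tr = abs(np.trace(gamma))
    if tr > 1e-8:
        raise RuntimeError(f"LCC correlation 1-RDM trace {tr:.2e} != 0")
    return gamma


def combine_rdm(reference_rdm: np.ndarray, lcc_rdm: np.ndarray) -> np.ndarray:
    """gamma = gamma(relaxed oo-pCCD reference) + gamma(unrelaxed LCC)."""
    if reference_rdm.shape != lcc_rdm.shape:
        raise ValueError("RDM basis/active-space mismatch")
    return reference_rdm + lcc_rdm
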