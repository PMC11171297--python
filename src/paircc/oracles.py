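"""Brute-force determinant-space machinery: dense FCI/DOCI, similarity-
transformed projections, and a synthetic pairing-model Hamiltonian.

Everything here is deliberately independent of the production solvers: the
Hamiltonian is built determinant by determinant with Slater-Condon rules,
cluster operators are applied as explicit sparse matrices, and densities are
contracted in second quantization.  The solver modules must agree with this
module on every small fixture; this module is never used at production scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse

from . import _slater
from .mo import MOIntegralSet

_DIM_CAP = 6000  # dense diagonalization guard


# ---------------------------------------------------------------------------
# determinant spaces
# ---------------------------------------------------------------------------
@dataclass
class DeterminantSpace:
    """All Sz=0 determinants of ``nelec`` electrons in ``norb`` spatial
    orbitals, optionally restricted to the seniority-zero (closed-pair)
    subspace."""

    norb: int
    nelec: int
    filter: str = "all"  # "all" | "seniority0"
    core: tuple = ()     # orbitals constrained doubly occupied

    def __post_init__(self):
        if self.nelec % 2:
            raise ValueError("Sz=0 spaces require an even electron count")
        core_mask = self._mask(self.core)
        active = [p for p in range(self.norb) if p not in set(self.core)]
        npair = self.nelec // 2 - len(self.core)
        if npair < 0:
            raise ValueError("core larger than the electron count")
        strings = [self._mask(c) | core_mask for c in
                   itertools.combinations(active, npair)]
        if self.filter == "seniority0":
            self.amasks = np.array(strings, dtype=np.int64)
            self.bmasks = self.amasks.copy()
        elif self.filter == "all":
            pairs = [(a, b) for a in strings for b in strings]
            self.amasks = np.array([p[0] for p in pairs], dtype=np.int64)
            self.bmasks = np.array([p[1] for p in pairs], dtype=np.int64)
        else:
            raise ValueError(f"unknown filter {self.filter!r}")
        self.index = {(a, b): i for i, (a, b)
                      in enumerate(zip(self.amasks, self.bmasks))}

    @staticmethod
    def _mask(orbs):
        m = 0
        for p in orbs:
            m |= 1 << p
        return m

    @property
    def dim(self):
        return len(self.amasks)

    def hf_index(self):
        m = self._mask(range(self.nelec // 2))
        return self.index[(m, m)]

    def rank(self, i):
        """Excitation rank (number of moved electrons) w.r.t. the reference."""
        ref = self._mask(range(self.nelec // 2))
        return (_bitcount(int(self.amasks[i]) & ~ref)
                + _bitcount(int(self.bmasks[i]) & ~ref))

    def seniority(self, i):
        return _bitcount(int(self.amasks[i]) ^ int(self.bmasks[i]))


def _bitcount(x):
    return bin(x).count("1")


def _single_sign(mask, hole, part):
    lo, hi = sorted((hole, part))
    return -1.0 if _bitcount(mask >> (lo + 1) & ((1 << (hi - lo - 1)) - 1)) % 2 else 1.0


# ---------------------------------------------------------------------------
# Hamiltonian and FCI
# ---------------------------------------------------------------------------
def build_dense_hamiltonian(moints: MOIntegralSet, space: DeterminantSpace):
    if space.dim > _DIM_CAP:
        raise ValueError(
            f"determinant space dimension {space.dim} exceeds the dense "
            f"oracle guard ({_DIM_CAP})")
    return _slater.build_hamiltonian(space.amasks, space.bmasks,
                                     moints.h, moints.eri_dense())


@dataclass
class FCIResult:
    energy: float           # total (includes core_energy)
    civec: np.ndarray
    space: DeterminantSpace
    rdm1: np.ndarray        # spin-summed, MO basis

    def electronic_dipole(self, dipole_mo=None):
        return np.einsum("pq,xpq->x", self.rdm1, dipole_mo)


def dense_fci(moints: MOIntegralSet, nelec: int, filter: str = "all",
              core=()) -> FCIResult:
    """Exact diagonalization in the chosen determinant space.

    Returns the ground state with its spin-summed 1-RDM.  ``core`` orbitals
    are constrained doubly occupied.  Refuses spaces beyond the dense
    dimension guard; all intended uses are tiny.
    """
    space = DeterminantSpace(moints.n, nelec, filter, tuple(core))
    H = build_dense_hamiltonian(moints, space)
    w, v = scipy.linalg.eigh(H)
    civec = v[:, 0]
    rdm1 = _slater.build_rdm1(space.amasks, space.bmasks,
                              np.ascontiguousarray(civec), moints.n)
    return FCIResult(energy=float(w[0]) + moints.core_energy, civec=civec,
                     space=space, rdm1=rdm1)


# ---------------------------------------------------------------------------
# operators as sparse matrices
# ---------------------------------------------------------------------------
def pair_excitation_matrix(space: DeterminantSpace, i: int, a: int):
    """P+_a P_i (move the (i-alpha, i-beta) pair to orbital a)."""
    rows, cols, vals = [], [], []
    for I, (am, bm) in enumerate(zip(space.amasks, space.bmasks)):
        am, bm = int(am), int(bm)
        bi, ba = 1 << i, 1 << a
        if (am & bi) and (bm & bi) and not (am & ba) and not (bm & ba):
            na = am & ~bi | ba
            nb = bm & ~bi | ba
            J = space.index.get((na, nb))
            if J is None:
                continue
            s = _single_sign(am, i, a) * _single_sign(bm, i, a)
            rows.append(J)
            cols.append(I)
            vals.append(s)
    return scipy.sparse.coo_matrix((vals, (rows, cols)),
                                   shape=(space.dim, space.dim)).tocsr()


def singlet_single_matrix(space: DeterminantSpace, i: int, a: int):
    """E_ai = a+_a,alpha a_i,alpha + a+_a,beta a_i,beta."""
    rows, cols, vals = [], [], []
    for I, (am, bm) in enumerate(zip(space.amasks, space.bmasks)):
        am, bm = int(am), int(bm)
        bi, ba = 1 << i, 1 << a
        if (am & bi) and not (am & ba):
            J = space.index.get((am & ~bi | ba, bm))
            if J is not None:
                rows.append(J)
                cols.append(I)
                vals.append(_single_sign(am, i, a))
        if (bm & bi) and not (bm & ba):
            J = space.index.get((am, bm & ~bi | ba))
            if J is not None:
                rows.append(J)
                cols.append(I)
                vals.append(_single_sign(bm, i, a))
    return scipy.sparse.coo_matrix((vals, (rows, cols)),
                                   shape=(space.dim, space.dim)).tocsr()


def pair_cluster_matrix(space: DeterminantSpace, tp: np.ndarray, n_pairs: int):
    """T_p = sum_ia t_ia P+_a P_i as a sparse matrix (reference partition:
    occupied pairs are orbitals 0..n_pairs-1)."""
    o, v = tp.shape
    T = scipy.sparse.csr_matrix((space.dim, space.dim))
    for i in range(o):
        for a in range(v):
            if tp[i, a] != 0.0:
                T = T + tp[i, a] * pair_excitation_matrix(space, i, n_pairs + a)
    return T


def apply_exp(T, vec, sign=1.0, tol=0.0):
    """exp(sign*T) @ vec for a nilpotent excitation operator T."""
    out = vec.copy()
    term = vec.copy()
    k = 0
    while True:
        k += 1
        term = sign * (T @ term) / k
        nrm = np.abs(term).max()
        if nrm <= tol:
            break
        out = out + term
        if k > 64:  # pragma: no cover - nilpotency guard
            raise RuntimeError("exp(T) expansion failed to terminate")
    return out


# ---------------------------------------------------------------------------
# seniority-zero (pair) space shortcuts
# ---------------------------------------------------------------------------
def projected_residual_check(tp: np.ndarray, moints: MOIntegralSet,
                             n_pairs: int) -> np.ndarray:
    """Pair-projected residuals <ia| e^-Tp H e^Tp |0> via explicit expansion
    of e^Tp|0> in the closed-pair determinant space.

    The Hamiltonian block is built by Slater-Condon rules over the
    seniority-zero determinants (projections of a seniority-zero ket onto
    seniority-zero bras only involve that block), fully independent of the
    closed-form pair equations being certified.
    """
    o, v = tp.shape
    space = DeterminantSpace(moints.n, 2 * n_pairs, "seniority0")
    H = build_dense_hamiltonian(moints, space)
    T = pair_cluster_matrix(space, tp, n_pairs)
    e0 = np.zeros(space.dim)
    e0[space.hf_index()] = 1.0
    w = apply_exp(-T, H @ apply_exp(T, e0))
    R = np.empty((o, v))
    ref = space._mask(range(n_pairs))
    for i in range(o):
        for a in range(v):
            m = ref & ~(1 << i) | (1 << (n_pairs + a))
            R[i, a] = w[space.index[(m, m)]]
    return R


# ---------------------------------------------------------------------------
# LCC determinant-space oracle
# ---------------------------------------------------------------------------
def lcc_manifold(space: DeterminantSpace, n_pairs: int):
    """Indices of rank-1 and rank-2 determinants, excluding the closed-pair
    (seniority-zero) doubles that belong to the pCCD channel."""
    idx = []
    for I in range(space.dim):
        r = space.rank(I)
        if r == 1:
            idx.append(I)
        elif r == 2:
            if space.seniority(I) == 0:   # P+_a P_i |0>: excluded pair channel
                continue
            idx.append(I)
    return np.array(idx, dtype=int)


def lcc_residual_vector(moints: MOIntegralSet, n_pairs: int, tp: np.ndarray,
                        Tprime):
    """<mu| Hbar + [Hbar, T'] |0> for all mu in the rank<=2 manifold.

    ``Tprime`` is a sparse matrix in the full determinant space (built from
    singlet singles/doubles operators by the caller).  Returns (manifold
    indices, residual components, Hbar(1+T')|0> vector).
    """
    space = DeterminantSpace(moints.n, 2 * n_pairs, "all")
    H = build_dense_hamiltonian(moints, space)
    T = pair_cluster_matrix(space, tp, n_pairs)

    def hbar(vec):
        return apply_exp(-T, H @ apply_exp(T, vec))

    e0 = np.zeros(space.dim)
    e0[space.hf_index()] = 1.0
    w = hbar(e0 + Tprime @ e0) - Tprime @ hbar(e0)
    man = lcc_manifold(space, n_pairs)
    return man, w[man], w, space


def build_tprime(space: DeterminantSpace, n_pairs: int, t1, t2):
    """T' = sum t1_ia E_ai + 1/2 sum' t2_ijab E_ai E_bj as a sparse matrix.

    t1 may be None (LCCD).  t2 must satisfy t2[i,i,a,a] = 0.
    """
    o = n_pairs
    v = space.norb - n_pairs
    E = {}
    for i in range(o):
        for a in range(v):
            E[i, a] = singlet_single_matrix(space, i, n_pairs + a)
    T = scipy.sparse.csr_matrix((space.dim, space.dim))
    if t1 is not None:
        for i in range(o):
            for a in range(v):
                if t1[i, a]:
                    T = T + t1[i, a] * E[i, a]
    if t2 is not None:
        for i in range(o):
            for j in range(o):
                for a in range(v):
                    for b in range(v):
                        tv = t2[i, j, a, b]
                        if tv:
                            T = T + 0.5 * tv * (E[i, a] @ E[j, b])
    return T


# ---------------------------------------------------------------------------
# generic spin-orbital second-quantized operators
# ---------------------------------------------------------------------------
def apply_so_ops(norb, amask, bmask, ops):
    """Apply a sequence of creation ('c') / annihilation ('a') operators of
    spin orbitals (alpha: p < norb, beta: p >= norb) to a determinant.

    Spin orbitals are globally ordered alpha-string-then-beta-string; the
    parity of a beta operator therefore includes the current alpha count.
    ``ops`` is applied right-to-left as written in the operator product.
    Returns (amask, bmask, phase) or None if the result vanishes.
    """
    phase = 1.0
    for kind, p in reversed(ops):
        if p < norb:
            mask, bit = amask, 1 << p
            below = _bitcount(amask & (bit - 1))
        else:
            s = p - norb
            mask, bit = bmask, 1 << s
            below = _bitcount(amask) + _bitcount(bmask & (bit - 1))
        if kind == "a":
            if not mask & bit:
                return None
        else:
            if mask & bit:
                return None
        mask ^= bit
        if below % 2:
            phase = -phase
        if p < norb:
            amask = mask
        else:
            bmask = mask
    return amask, bmask, phase


def so_op_matrix(space: DeterminantSpace, ops):
    """Sparse matrix of a normal product of so creation/annihilation ops."""
    rows, cols, vals = [], [], []
    for I, (am, bm) in enumerate(zip(space.amasks, space.bmasks)):
        out = apply_so_ops(space.norb, int(am), int(bm), ops)
        if out is None:
            continue
        J = space.index.get((out[0], out[1]))
        if J is None:
            continue
        rows.append(J)
        cols.append(I)
        vals.append(out[2])
    return scipy.sparse.coo_matrix((vals, (rows, cols)),
                                   shape=(space.dim, space.dim)).tocsr()


def so_cluster_matrix(space: DeterminantSpace, occ_so, virt_so, t1, t2):
    """T = sum t1_ia a+_a a_i + 1/4 sum t2_ijab a+_a a+_b a_j a_i over spin
    orbitals (lists ``occ_so``/``virt_so`` give the so indices the amplitude
    axes refer to)."""
    T = scipy.sparse.csr_matrix((space.dim, space.dim))
    if t1 is not None:
        for i, iso in enumerate(occ_so):
            for a, aso in enumerate(virt_so):
                if t1[i, a]:
                    T = T + t1[i, a] * so_op_matrix(
                        space, [("c", aso), ("a", iso)])
    if t2 is not None:
        no, nv = len(occ_so), len(virt_so)
        for i in range(no):
            for j in range(i + 1, no):
                for a in range(nv):
                    for b in range(a + 1, nv):
                        tv = t2[i, j, a, b]
                        if tv:
                            T = T + tv * so_op_matrix(
                                space, [("c", virt_so[a]), ("c", virt_so[b]),
                                        ("a", occ_so[j]), ("a", occ_so[i])])
    return T


def so_projection_tensors(space: DeterminantSpace, occ_so, virt_so, w):
    """Read a determinant-space vector ``w`` back into spin-orbital residual
    tensors R1[i,a] = <Phi_i^a|w> and R2[i,j,a,b] = <Phi_ij^ab|w> with
    Phi_ij^ab = a+_a a+_b a_j a_i |0>."""
    no, nv = len(occ_so), len(virt_so)
    ref_a = space._mask(range(space.nelec // 2))
    ref = (int(ref_a), int(ref_a))
    R1 = np.zeros((no, nv), dtype=w.dtype)
    R2 = np.zeros((no, no, nv, nv), dtype=w.dtype)
    for i, iso in enumerate(occ_so):
        for a, aso in enumerate(virt_so):
            out = apply_so_ops(space.norb, ref[0], ref[1],
                               [("c", aso), ("a", iso)])
            if out is None:
                continue
            J = space.index.get((out[0], out[1]))
            if J is not None:
                R1[i, a] = out[2] * w[J]
    for i in range(no):
        for j in range(i + 1, no):
            for a in range(nv):
                for b in range(a + 1, nv):
                    out = apply_so_ops(
                        space.norb, ref[0], ref[1],
                        [("c", virt_so[a]), ("c", virt_so[b]),
                         ("a", occ_so[j]), ("a", occ_so[i])])
                    if out is None:
                        continue
                    J = space.index.get((out[0], out[1]))
                    if J is None:
                        continue
                    val = out[2] * w[J]
                    R2[i, j, a, b] = val
                    R2[j, i, a, b] = -val
                    R2[i, j, b, a] = -val
                    R2[j, i, b, a] = val
    return R1, R2


def spinorb_tensors(moints: MOIntegralSet, n_pairs: int):
    """Fock and antisymmetrized two-electron so tensors, ordered with all
    occupied spin orbitals (alpha occ then beta occ) first."""
    n = moints.n
    o = n_pairs
    eri = moints.eri_dense()
    f = moints.fock(o)
    # so order: alpha occ, beta occ, alpha virt, beta virt
    order = ([("a", p) for p in range(o)] + [("b", p) for p in range(o)]
             + [("a", p) for p in range(o, n)] + [("b", p) for p in range(o, n)])
    nso = 2 * n
    f_so = np.zeros((nso, nso))
    spins = np.array([0 if s == "a" else 1 for s, _ in order])
    spat = np.array([p for _, p in order])
    same = spins[:, None] == spins[None, :]
    f_so = f[np.ix_(spat, spat)] * same
    w = eri[np.ix_(spat, spat, spat, spat)]
    coul = np.einsum("prqs->pqrs", w)
    exch = np.einsum("psqr->pqrs", w)
    d_pr = same
    v_so = (coul * (d_pr[:, None, :, None] * same[None, :, None, :])
            - exch * (same[:, None, None, :] * same[None, :, :, None]))
    return f_so, v_so, order


def so_index_maps(n: int, n_pairs: int):
    """so indices (in the 0..2n-1 alpha/beta block convention) of the
    occupied and virtual spin orbitals, matching ``spinorb_tensors`` order."""
    o = n_pairs
    occ_so = list(range(o)) + [n + p for p in range(o)]
    virt_so = list(range(o, n)) + [n + p for p in range(o, n)]
    return occ_so, virt_so


# ---------------------------------------------------------------------------
# synthetic pairing-model Hamiltonian
# ---------------------------------------------------------------------------
def make_pairing_hamiltonian(levels, G, seed=None, jitter=0.0) -> MOIntegralSet:
    """Reduced-BCS pairing model as an electronic-integral set.

    H = sum_p 2 eps_p N_p - G sum_pq P+_p P_q, realized with
    (pp|pp) = -G, (pq|pq) = -G and (pp|qq) = -G/2 for p != q, so that the
    closed-pair determinant energies carry no spurious cross terms.
    Seniority is conserved by construction.  ``jitter`` adds seeded
    level noise for non-degenerate spectra.
    """
    levels = np.asarray(levels, dtype=float).copy()
    if G < 0:
        raise ValueError("pair coupling G must be >= 0")
    if jitter:
        rng = np.random.default_rng(seed)
        levels = levels + jitter * rng.standard_normal(levels.size)
    n = levels.size
    h = np.diag(levels)
    eri = np.zeros((n, n, n, n))
    for p in range(n):
        eri[p, p, p, p] = -G
        for q in range(n):
            if p == q:
                continue
            eri[p, q, p, q] = eri[q, p, q, p] = -G
            eri[p, q, q, p] = eri[q, p, p, q] = -G
            eri[p, p, q, q] = -G / 2.0
    return MOIntegralSet(h=h, core_energy=0.0, eri=eri)
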