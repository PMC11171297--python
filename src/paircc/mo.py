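"""MO-basis integral containers, AO->MO transformation and frozen-core folding.

The central container is :class:`MOIntegralSet`: an effective one-electron
matrix ``h`` (with any frozen-core mean field folded in), the two-electron
repulsion integrals in chemists' notation ``(pq|rs)`` held either dense or as
Cholesky factors, a scalar ``core_energy`` (nuclear repulsion plus, after
folding, the frozen-core energy) and optionally the three Cartesian dipole
matrices.  The pair solvers only ever see this object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MOCoefficients:
    """AO->MO coefficient matrix with a frozen-core/active partition.

    ``frozen_core``, ``occupied_pairs`` and ``virtuals`` are lists of MO
    column indices; together they partition all MOs, and
    2*(len(frozen_core)+len(occupied_pairs)) equals the electron count.
    """

    C: np.ndarray
    frozen_core: list
    occupied_pairs: list
    virtuals: list

    def __post_init__(self):
        n = self.C.shape[1]
        allidx = sorted(list(self.frozen_core) + list(self.occupied_pairs)
                        + list(self.virtuals))
        if allidx != list(range(n)):
            raise ValueError("frozen_core/occupied_pairs/virtuals must partition MOs")

    @property
    def n_mo(self):
        return self.C.shape[1]

    def check_orthonormal(self, S, tol=1e-10):
        dev = np.abs(self.C.T @ S @ self.C - np.eye(self.n_mo)).max()
        if dev > tol:
            raise ValueError(f"MO coefficients not S-orthonormal (dev {dev:.2e})")


@dataclass
class MOIntegralSet:
    """Molecular-orbital integrals.  ``eri`` dense (pq|rs) or ``chol`` (m,n,n)."""

    h: np.ndarray
    core_energy: float = 0.0
    eri: np.ndarray | None = None
    chol: np.ndarray | None = None
    dipole: np.ndarray | None = None        # (3, n, n)

    def __post_init__(self):
        if self.eri is None and self.chol is None:
            raise ValueError("need dense eri or Cholesky factors")

    @property
    def n(self):
        return self.h.shape[0]

    # -- two-electron access ------------------------------------------------
    def eri_dense(self):
        if self.eri is not None:
            return self.eri
        return np.einsum("Ppq,Prs->pqrs", self.chol, self.chol, optimize=True)

    def jk_matrices(self):
        """J_pq = (pp|qq) and K_pq = (pq|pq) -- all pCCD needs."""
        if self.eri is not None:
            J = np.einsum("ppqq->pq", self.eri)
            K = np.einsum("pqpq->pq", self.eri)
        else:
            d = np.einsum("Ppp->Pp", self.chol)
            J = np.einsum("Pp,Pq->pq", d, d)
            K = np.einsum("Ppq,Ppq->pq", self.chol, self.chol)
        return J, K

    def block(self, s1, s2, s3, s4):
        """Chemists' block (s1 s2 | s3 s4) for index arrays/slices."""
        if self.eri is not None:
            return self.eri[np.ix_(s1, s2, s3, s4)]
        L1 = self.chol[:, s1][:, :, s2]
        L2 = self.chol[:, s3][:, :, s4]
        return np.einsum("Ppq,Prs->pqrs", L1, L2, optimize=True)

    def fock(self, n_occ):
        """Closed-shell Fock matrix for the first ``n_occ`` doubly occupied MOs."""
        o = np.arange(n_occ)
        if self.eri is not None:
            J = np.einsum("pqjj->pq", self.eri[:, :, o][:, :, :, o])
            K = np.einsum("pjjq->pq", self.eri[:, o][:, :, o, :])
        else:
            Lo = self.chol[:, :, o]
            J = np.einsum("Pjj,Ppq->pq", Lo[:, o], self.chol, optimize=True)
            K = np.einsum("Ppj,Pqj->pq", Lo, Lo, optimize=True)
        return self.h + 2.0 * J - K

    def scf_energy(self, n_occ):
        f = self.fock(n_occ)
        o = np.arange(n_occ)
        return self.core_energy + (self.h[o, o] + f[o, o]).sum()

    # -- basis changes ------------------------------------------------------
    def rotate(self, U):
        """Rotate all tensors into the basis C' = C U."""
        h = U.T @ self.h @ U
        eri = chol = dip = None
        if self.eri is not None:
            eri = np.einsum("pqrs,pi,qj,rk,sl->ijkl", self.eri, U, U, U, U,
                            optimize=True)
        if self.chol is not None:
            chol = _rotate_chol(self.chol, U)
        if self.dipole is not None:
            dip = np.einsum("xpq,pi,qj->xij", self.dipole, U, U, optimize=True)
        return MOIntegralSet(h=h, core_energy=self.core_energy, eri=eri,
                             chol=chol, dipole=dip)


def _rotate_chol(L, C):
    """L^P -> C^T L^P C via two GEMMs per stacked factor."""
    m, n, _ = L.shape
    nc = C.shape[1]
    t1 = (L.reshape(m * n, n) @ C).reshape(m, n, nc)
    t1 = np.ascontiguousarray(t1.transpose(0, 2, 1)).reshape(m * nc, n)
    out = (t1 @ C).reshape(m, nc, nc)
    # each C^T L^P C is symmetric (L^P symmetric), so no back-transpose
    return out


def transform_to_mo(aoints, C) -> MOIntegralSet:
    """Transform an AOIntegralSet into the MO basis given AO->MO matrix C.

    The four-index transform runs one index at a time (O(N^5)); Cholesky
    factors are transformed as L^P -> C^T L^P C.
    """
    n_ao = aoints.n_basis
    if C.shape[0] != n_ao:
        raise ValueError("dimension mismatch between AO integrals and C")
    h = C.T @ aoints.core_hamiltonian @ C
    dip = np.einsum("xpq,pi,qj->xij", aoints.dipole_ints, C, C, optimize=True)
    eri = chol = None
    if aoints.chol is not None:
        chol = _rotate_chol(aoints.chol.vectors, C)
    else:
        eri = aoints.eri
        for _ in range(4):  # one index per pass; new MO index appended last
            eri = np.tensordot(eri, C, axes=([0], [0]))
    return MOIntegralSet(h=h, core_energy=aoints.nuclear_repulsion, eri=eri,
                         chol=chol, dipole=dip)


def fold_frozen_core(moints: MOIntegralSet, frozen_core) -> MOIntegralSet:
    """Fold doubly occupied frozen orbitals into h and the core energy.

    The effective one-electron operator gains the Coulomb-minus-half-exchange
    mean field of the frozen orbitals (restricted closed-shell folding), the
    core energy gains the frozen-core energy, and all tensors are re-indexed
    to the active space.  The frozen orbitals' own dipole contribution
    (2 sum_c d_cc) is NOT added here; the properties layer adds it back.
    """
    frozen = sorted(frozen_core)
    if not frozen:
        return moints
    n = moints.n
    active = [p for p in range(n) if p not in frozen]
    if len(active) + len(frozen) != n:
        raise ValueError("frozen set overlaps or exceeds MO range")
    c = np.array(frozen)

    if moints.eri is not None:
        Jc = np.einsum("pqcc->pq", moints.eri[:, :, c][:, :, :, c])
        Kc = np.einsum("pccq->pq", moints.eri[:, c][:, :, c, :])
    else:
        Lc = moints.chol[:, :, c]
        Jc = np.einsum("Pcc,Ppq->pq", Lc[:, c], moints.chol, optimize=True)
        Kc = np.einsum("Ppc,Pqc->pq", Lc, Lc, optimize=True)
    heff = moints.h + 2.0 * Jc - Kc
    e_core = (moints.h[c, c] + heff[c, c]).sum() + moints.core_energy

    a = np.array(active)
    eri = chol = dip = None
    if moints.eri is not None:
        eri = moints.eri[np.ix_(a, a, a, a)]
    else:
        chol = moints.chol[:, a][:, :, a]
    if moints.dipole is not None:
        dip = moints.dipole[:, a][:, :, a]
    return MOIntegralSet(h=heff[np.ix_(a, a)], core_energy=float(e_core),
                         eri=eri, chol=chol, dipole=dip)
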