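"""AO integral sets: assembly driver over the McMurchie-Davidson kernels,
Cholesky decomposition of the ERI, and static embedding potentials."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg.lapack

from .basis import C2S, build_shells, atom_ao_map
from . import engine


@dataclass
class CholeskyFactors:
    """Two-electron integrals as (pq|rs) ~ sum_P L^P_pq L^P_rs."""

    vectors: np.ndarray     # (rank, n, n), each symmetric
    threshold: float

    @property
    def rank(self):
        return self.vectors.shape[0]


@dataclass
class AOIntegralSet:
    overlap: np.ndarray
    kinetic: np.ndarray
    nuclear: np.ndarray
    dipole_ints: np.ndarray          # (3, n, n)
    nuclear_repulsion: float
    origin: np.ndarray
    eri: np.ndarray | None = None
    chol: CholeskyFactors | None = None
    v_embedding: np.ndarray | None = None
    shells: list = field(default_factory=list)
    atom_map: np.ndarray | None = None

    @property
    def n_basis(self):
        return self.overlap.shape[0]

    @property
    def core_hamiltonian(self):
        h = self.kinetic + self.nuclear
        if self.v_embedding is not None:
            h = h + self.v_embedding
        return h

    def eri_dense(self):
        if self.eri is not None:
            return self.eri
        L = self.chol.vectors
        return np.einsum("Ppq,Prs->pqrs", L, L, optimize=True)


def add_embedding_potential(aoints: AOIntegralSet,
                            v_emb: np.ndarray) -> AOIntegralSet:
    """Add a precomputed static one-electron embedding potential to the core
    Hamiltonian; everything downstream is unchanged."""
    v = np.asarray(v_emb, float)
    n = aoints.n_basis
    if v.shape != (n, n):
        raise ValueError(f"embedding potential must be {n}x{n}")
    if np.abs(v - v.T).max() > 1e-10:
        raise ValueError("embedding potential must be symmetric")
    new = AOIntegralSet(**{**aoints.__dict__})
    new.v_embedding = v if aoints.v_embedding is None \
        else aoints.v_embedding + v
    return new


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------
def _sph(shell):
    return C2S[shell.l]


def build_one_electron(molecule, shells, origin):
    nao = sum(s.n_sph for s in shells)
    S = np.zeros((nao, nao))
    T = np.zeros((nao, nao))
    V = np.zeros((nao, nao))
    D = np.zeros((3, nao, nao))
    offs = np.cumsum([0] + [s.n_sph for s in shells])
    charges = molecule.nuclear_charges
    centers = molecule.coords
    for i, si in enumerate(shells):
        Ti = _sph(si)
        for j, sj in enumerate(shells[:i + 1]):
            Tj = _sph(sj)
            Sc, Tc, Vc, Dc = engine.one_electron_pair(
                si.l, sj.l, si.center, sj.center, si.exps, si.coefs,
                sj.exps, sj.coefs, charges, centers, origin, engine._CARTS)
            sl_i = slice(offs[i], offs[i + 1])
            sl_j = slice(offs[j], offs[j + 1])
            for M, Mc in ((S, Sc), (T, Tc), (V, Vc)):
                blk = Ti @ Mc @ Tj.T
                M[sl_i, sl_j] = blk
                M[sl_j, sl_i] = blk.T
            for x in range(3):
                blk = Ti @ Dc[x] @ Tj.T
                D[x, sl_i, sl_j] = blk
                D[x, sl_j, sl_i] = blk.T
    return S, T, V, D


def cross_overlap(shells_a, shells_b):
    """Overlap matrix <chi_a | chi_b> between two shell sets (possibly at
    different geometries) -- used to propagate orbitals along scans."""
    na = sum(s.n_sph for s in shells_a)
    nb = sum(s.n_sph for s in shells_b)
    S = np.zeros((na, nb))
    offa = np.cumsum([0] + [s.n_sph for s in shells_a])
    offb = np.cumsum([0] + [s.n_sph for s in shells_b])
    nochg = np.zeros(0)
    nocen = np.zeros((0, 3))
    for i, si in enumerate(shells_a):
        for j, sj in enumerate(shells_b):
            Sc, _, _, _ = engine.one_electron_pair(
                si.l, sj.l, si.center, sj.center, si.exps, si.coefs,
                sj.exps, sj.coefs, nochg, nocen, np.zeros(3), engine._CARTS)
            S[offa[i]:offa[i + 1], offb[j]:offb[j + 1]] = \
                _sph(si) @ Sc @ _sph(sj).T
    return S


def build_eri(shells, screen=1e-14):
    """Full spherical ERI tensor with Schwarz screening."""
    nao = sum(s.n_sph for s in shells)
    offs = np.cumsum([0] + [s.n_sph for s in shells])
    ns = len(shells)
    eri = np.zeros((nao, nao, nao, nao))

    def quartet(i, j, k, l):
        si, sj, sk, sl = shells[i], shells[j], shells[k], shells[l]
        blk = engine.eri_quartet(
            si.l, sj.l, sk.l, sl.l, si.center, sj.center, sk.center,
            sl.center, si.exps, si.coefs, sj.exps, sj.coefs,
            sk.exps, sk.coefs, sl.exps, sl.coefs, engine._CARTS)
        blk = np.einsum("pi,qj,rk,sl,ijkl->pqrs", _sph(si), _sph(sj),
                        _sph(sk), _sph(sl), blk, optimize=True)
        return blk

    # Schwarz bounds per shell pair
    qbound = np.zeros((ns, ns))
    for i in range(ns):
        for j in range(i + 1):
            blk = quartet(i, j, i, j)
            ni, nj = shells[i].n_sph, shells[j].n_sph
            diag = blk.reshape(ni * nj, ni * nj).diagonal()
            qbound[i, j] = qbound[j, i] = np.sqrt(np.abs(diag).max())

    for i in range(ns):
        for j in range(i + 1):
            for k in range(i + 1):
                lmax = j if k == i else k
                for l in range(lmax + 1):
                    if qbound[i, j] * qbound[k, l] < screen:
                        continue
                    blk = quartet(i, j, k, l)
                    _scatter(eri, blk, offs, i, j, k, l)
    return eri


def _scatter(eri, blk, offs, i, j, k, l):
    sl = [slice(offs[x], offs[x + 1]) for x in (i, j, k, l)]
    eri[sl[0], sl[1], sl[2], sl[3]] = blk
    eri[sl[1], sl[0], sl[2], sl[3]] = blk.transpose(1, 0, 2, 3)
    eri[sl[0], sl[1], sl[3], sl[2]] = blk.transpose(0, 1, 3, 2)
    eri[sl[1], sl[0], sl[3], sl[2]] = blk.transpose(1, 0, 3, 2)
    eri[sl[2], sl[3], sl[0], sl[1]] = blk.transpose(2, 3, 0, 1)
    eri[sl[3], sl[2], sl[0], sl[1]] = blk.transpose(3, 2, 0, 1)
    eri[sl[2], sl[3], sl[1], sl[0]] = blk.transpose(2, 3, 1, 0)
    eri[sl[3], sl[2], sl[1], sl[0]] = blk.transpose(3, 2, 1, 0)


def cholesky_decompose(eri: np.ndarray, threshold: float = 1e-5
                       ) -> CholeskyFactors:
    """Pivoted incomplete Cholesky of the (pq)x(rs) ERI matrix.

    Stops when the largest remaining diagonal element is <= threshold, so
    every diagonal (mu nu|mu nu) of the reconstruction errs by at most the
    threshold.  Uses LAPACK dpstrf (full diagonal pivoting).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = eri.shape[0]
    M = np.ascontiguousarray(eri.reshape(n * n, n * n))
    dmax = M.diagonal().max()
    if dmax <= threshold:
        return CholeskyFactors(np.zeros((0, n, n)), threshold)
    if dmax < 0:
        raise ValueError("ERI matrix has a negative diagonal: not PSD")
    c, piv, rank, info = scipy.linalg.lapack.dpstrf(M, tol=threshold,
                                                    lower=1)
    if info < 0:  # pragma: no cover
        raise RuntimeError(f"dpstrf failed (info={info})")
    piv = piv - 1
    Lfull = np.tril(c)[:, :rank]
    L = np.zeros((n * n, rank))
    L[piv] = Lfull
    return CholeskyFactors(np.ascontiguousarray(L.T.reshape(rank, n, n)),
                           threshold)


# ---------------------------------------------------------------------------
# top-level builder
# ---------------------------------------------------------------------------
def build_from_backend(molecule, basis_name, origin=None, store="dense",
                       cholesky_threshold=1e-5) -> AOIntegralSet:
    """Compute all AO integrals for a molecule with the built-in engine.

    ``store='cholesky'`` replaces the dense ERI tensor with pivoted
    Cholesky factors at the given threshold (default 1e-5).
    Dipole integrals are about ``origin`` (default: coordinate origin).
    """
    origin = np.zeros(3) if origin is None else np.asarray(origin, float)
    shells = build_shells(molecule, basis_name)
    S, T, V, D = build_one_electron(molecule, shells, origin)
    eri = build_eri(shells)
    out = AOIntegralSet(
        overlap=S, kinetic=T, nuclear=V, dipole_ints=D,
        nuclear_repulsion=molecule.nuclear_repulsion(), origin=origin,
        shells=shells, atom_map=atom_ao_map(shells))
    if store == "cholesky":
        out.chol = cholesky_decompose(eri, cholesky_threshold)
    elif store == "dense":
        out.eri = eri
    else:
        raise ValueError("store must be 'dense' or 'cholesky'")
    return out
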