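"""Numba kernels for determinant-space (FCI) Hamiltonian and density builds.

Determinants are (alpha, beta) occupation bitmasks in int64, with the
convention that creation operators are ordered by ascending orbital index,
alpha string before beta string; excitation phases then factorize into
independent per-spin-string parities.
"""

import numba
import numpy as np


@numba.njit(cache=True, inline="always")
def _popcount(x):
    n = 0
    while x:
        x &= x - 1
        n += 1
    return n


@numba.njit(cache=True, inline="always")
def _bits_between(mask, p, q):
    lo, hi = (p, q) if p < q else (q, p)
    if hi - lo < 2:
        return 0
    seg = (mask >> (lo + 1)) & ((numba.int64(1) << (hi - lo - 1)) - 1)
    return _popcount(seg)


@numba.njit(cache=True, inline="always")
def _single_sign(mask, hole, part):
    return -1.0 if _bits_between(mask, hole, part) % 2 else 1.0


@numba.njit(cache=True)
def _occ_list(mask, out):
    n = 0
    p = 0
    while mask:
        if mask & 1:
            out[n] = p
            n += 1
        mask >>= 1
        p += 1
    return n


@numba.njit(cache=True)
def _diff_orbs(m1, m2, holes, parts):
    """Orbitals occupied in m1 not m2 (holes) and vice versa (parts)."""
    d = m1 ^ m2
    nh = _occ_list(d & m1, holes)
    np_ = _occ_list(d & m2, parts)
    return nh, np_


@numba.njit(cache=True)
def _diag_element(amask, bmask, h, eri, occa, occb):
    na = _occ_list(amask, occa)
    nb = _occ_list(bmask, occb)
    e = 0.0
    for ii in range(na):
        p = occa[ii]
        e += h[p, p]
        for jj in range(ii):
            q = occa[jj]
            e += eri[p, p, q, q] - eri[p, q, q, p]
    for ii in range(nb):
        p = occb[ii]
        e += h[p, p]
        for jj in range(ii):
            q = occb[jj]
            e += eri[p, p, q, q] - eri[p, q, q, p]
    for ii in range(na):
        for jj in range(nb):
            e += eri[occa[ii], occa[ii], occb[jj], occb[jj]]
    return e


@numba.njit(cache=True)
def _single_element(samemask, othermask, p, q, h, eri, occs, occo):
    """<D1|H|D2> for a single excitation p(in D1) -> q(in D2), same spin
    string ``samemask`` (taken from D1), other-spin string ``othermask``."""
    ns = _occ_list(samemask, occs)
    no = _occ_list(othermask, occo)
    x = h[p, q]
    for ii in range(ns):
        r = occs[ii]
        if r == p:
            continue
        x += eri[p, q, r, r] - eri[p, r, r, q]
    for ii in range(no):
        r = occo[ii]
        x += eri[p, q, r, r]
    return x * _single_sign(samemask, p, q)


@numba.njit(cache=True)
def build_hamiltonian(amasks, bmasks, h, eri):
    dim = amasks.shape[0]
    H = np.zeros((dim, dim))
    norb = h.shape[0]
    occa = np.empty(norb, np.int64)
    occb = np.empty(norb, np.int64)
    holes = np.empty(4, np.int64)
    parts = np.empty(4, np.int64)
    for I in range(dim):
        aI, bI = amasks[I], bmasks[I]
        H[I, I] = _diag_element(aI, bI, h, eri, occa, occb)
        for J in range(I):
            aJ, bJ = amasks[J], bmasks[J]
            nda = _popcount(aI ^ aJ)
            ndb = _popcount(bI ^ bJ)
            if nda + ndb > 4:
                continue
            x = 0.0
            if nda == 2 and ndb == 0:
                _diff_orbs(aI, aJ, holes, parts)
                x = _single_element(aI, bI, holes[0], parts[0], h, eri, occa, occb)
            elif nda == 0 and ndb == 2:
                _diff_orbs(bI, bJ, holes, parts)
                x = _single_element(bI, aI, holes[0], parts[0], h, eri, occa, occb)
            elif nda == 2 and ndb == 2:
                _diff_orbs(aI, aJ, holes, parts)
                pa, qa = holes[0], parts[0]
                _diff_orbs(bI, bJ, holes, parts)
                pb, qb = holes[0], parts[0]
                x = (eri[pa, qa, pb, qb]
                     * _single_sign(aI, pa, qa) * _single_sign(bI, pb, qb))
            elif nda == 4 and ndb == 0:
                _diff_orbs(aI, aJ, holes, parts)
                p1, p2, q1, q2 = holes[0], holes[1], parts[0], parts[1]
                x = eri[p1, q1, p2, q2] - eri[p1, q2, p2, q1]
                # sequential application: p1->q1 on aI, then p2->q2
                s = _single_sign(aI, p1, q1)
                m = (aI & ~(numba.int64(1) << p1)) | (numba.int64(1) << q1)
                s *= _single_sign(m, p2, q2)
                x *= s
            elif nda == 0 and ndb == 4:
                _diff_orbs(bI, bJ, holes, parts)
                p1, p2, q1, q2 = holes[0], holes[1], parts[0], parts[1]
                x = eri[p1, q1, p2, q2] - eri[p1, q2, p2, q1]
                s = _single_sign(bI, p1, q1)
                m = (bI & ~(numba.int64(1) << p1)) | (numba.int64(1) << q1)
                s *= _single_sign(m, p2, q2)
                x *= s
            H[I, J] = x
            H[J, I] = x
    return H


@numba.njit(cache=True)
def build_rdm1(amasks, bmasks, civec, norb):
    """Spin-summed one-particle density <Psi|E_pq|Psi> (symmetric for real CI)."""
    dim = amasks.shape[0]
    rdm = np.zeros((norb, norb))
    occa = np.empty(norb, np.int64)
    holes = np.empty(2, np.int64)
    parts = np.empty(2, np.int64)
    for I in range(dim):
        cI = civec[I]
        if cI == 0.0:
            continue
        na = _occ_list(amasks[I], occa)
        for ii in range(na):
            rdm[occa[ii], occa[ii]] += cI * cI
        na = _occ_list(bmasks[I], occa)
        for ii in range(na):
            rdm[occa[ii], occa[ii]] += cI * cI
        for J in range(I):
            nda = _popcount(amasks[I] ^ amasks[J])
            ndb = _popcount(bmasks[I] ^ bmasks[J])
            if nda + ndb != 2:
                continue
            if nda == 2:
                _diff_orbs(amasks[I], amasks[J], holes, parts)
                s = _single_sign(amasks[I], holes[0], parts[0])
            else:
                _diff_orbs(bmasks[I], bmasks[J], holes, parts)
                s = _single_sign(bmasks[I], holes[0], parts[0])
            v = s * cI * civec[J]
            rdm[holes[0], parts[0]] += v
            rdm[parts[0], holes[0]] += v
    return rdm
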