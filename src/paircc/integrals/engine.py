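"""McMurchie-Davidson Gaussian integrals (numba-accelerated).

Implements overlap, kinetic, dipole, nuclear-attraction and electron
repulsion integrals over contracted Cartesian Gaussians via Hermite
expansion coefficients E_t^{ij} and Hermite Coulomb integrals R_tuv, with
Schwarz screening for the ERI tensor.  The scope is deliberately modest
(l <= 3, no derivatives, no symmetry beyond permutational): it exists so the
package can build AO integrals for small molecules self-contained.
"""

from __future__ import annotations

import numba
import numpy as np

from .basis import cartesian_components, n_cart

LMAX = 3
NCMAX = n_cart(LMAX)

_CARTS = np.zeros((LMAX + 1, NCMAX, 3), dtype=np.int64)
for _l in range(LMAX + 1):
    for _i, c in enumerate(cartesian_components(_l)):
        _CARTS[_l, _i] = c


# ---------------------------------------------------------------------------
# Boys function
# ---------------------------------------------------------------------------
@numba.njit(cache=True)
def boys(T, mmax, out):
    if T < 1e-13:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2 * m + 1)
        return
    if T < 35.0:
        expT = np.exp(-T)
        # series for the highest order, then downward recursion
        term = 1.0 / (2 * mmax + 1)
        s = term
        k = 1
        while True:
            term *= 2.0 * T / (2 * mmax + 2 * k + 1)
            s += term
            if term < 1e-17 * s:
                break
            k += 1
        out[mmax] = expT * s
        for m in range(mmax - 1, -1, -1):
            out[m] = (2.0 * T * out[m + 1] + expT) / (2 * m + 1)
    else:
        expT = np.exp(-T)
        out[0] = 0.5 * np.sqrt(np.pi / T)
        for m in range(mmax):
            out[m + 1] = ((2 * m + 1) * out[m] - expT) / (2.0 * T)


# ---------------------------------------------------------------------------
# 1D Hermite expansion coefficients
# ---------------------------------------------------------------------------
@numba.njit(cache=True)
def hermite_E(la, lb, a, b, AB, out):
    """Fill out[i, j, t] = E_t^{ij} for one dimension (includes the
    Gaussian product prefactor exp(-mu AB^2))."""
    p = a + b
    mu = a * b / p
    out[:, :, :] = 0.0
    out[0, 0, 0] = np.exp(-mu * AB * AB)
    Xpa = -b * AB / p      # P - A
    Xpb = a * AB / p       # P - B
    for i in range(la + 1):
        for j in range(lb + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                # build from (i-1, 0)
                for t in range(i + j + 1):
                    v = Xpa * out[i - 1, 0, t]
                    if t > 0:
                        v += out[i - 1, 0, t - 1] / (2.0 * p)
                    if t + 1 <= i + j:
                        v += (t + 1) * out[i - 1, 0, t + 1]
                    out[i, 0, t] = v
            else:
                for t in range(i + j + 1):
                    v = Xpb * out[i, j - 1, t]
                    if t > 0:
                        v += out[i, j - 1, t - 1] / (2.0 * p)
                    if t + 1 <= i + j:
                        v += (t + 1) * out[i, j - 1, t + 1]
                    out[i, j, t] = v


# ---------------------------------------------------------------------------
# Hermite Coulomb integrals
# ---------------------------------------------------------------------------
@numba.njit(cache=True)
def hermite_R(L, p, X, Y, Z, out):
    """out[t,u,v] = R_tuv(p, (X,Y,Z)) for t+u+v <= L."""
    T = p * (X * X + Y * Y + Z * Z)
    F = np.empty(L + 1)
    boys(T, L, F)
    Rn = np.zeros((L + 1, L + 1, L + 1, L + 1))
    for n in range(L + 1):
        Rn[n, 0, 0, 0] = (-2.0 * p) ** n * F[n]
    for total in range(1, L + 1):
        for n in range(L - total + 1):
            for t in range(total + 1):
                for u in range(total - t + 1):
                    v = total - t - u
                    if t > 0:
                        val = X * Rn[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * Rn[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = Y * Rn[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * Rn[n + 1, t, u - 2, v]
                    else:
                        val = Z * Rn[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * Rn[n + 1, t, u, v - 2]
                    Rn[n, t, u, v] = val
    out[:L + 1, :L + 1, :L + 1] = Rn[0]


# ---------------------------------------------------------------------------
# one-electron integrals (per shell pair, Cartesian blocks)
# ---------------------------------------------------------------------------
@numba.njit(cache=True)
def _overlap_1d(E, i, j, p):
    return E[i, j, 0] * np.sqrt(np.pi / p)


@numba.njit(cache=True)
def one_electron_pair(la, lb, A, B, exps_a, coefs_a, exps_b, coefs_b,
                      charges, centers, origin, carts):
    """Returns (S, T, V, D) Cartesian blocks for one shell pair.
    S overlap, T kinetic, V nuclear attraction (negative sign included),
    D three dipole blocks about ``origin``."""
    nca, ncb = (la + 1) * (la + 2) // 2, (lb + 1) * (lb + 2) // 2
    S = np.zeros((nca, ncb))
    Tk = np.zeros((nca, ncb))
    V = np.zeros((nca, ncb))
    D = np.zeros((3, nca, ncb))
    # E tables with room for lb+2 (kinetic) and la+1 (dipole)
    dim_a = la + 2
    dim_b = lb + 3
    Ex = np.zeros((dim_a, dim_b, dim_a + dim_b))
    Ey = np.zeros((dim_a, dim_b, dim_a + dim_b))
    Ez = np.zeros((dim_a, dim_b, dim_a + dim_b))
    Ltot = la + lb
    R = np.zeros((Ltot + 1, Ltot + 1, Ltot + 1))
    for ka in range(exps_a.shape[0]):
        a = exps_a[ka]
        ca = coefs_a[ka]
        for kb in range(exps_b.shape[0]):
            b = exps_b[kb]
            cb = coefs_b[kb]
            p = a + b
            hermite_E(la + 1, lb + 2, a, b, A[0] - B[0], Ex)
            hermite_E(la + 1, lb + 2, a, b, A[1] - B[1], Ey)
            hermite_E(la + 1, lb + 2, a, b, A[2] - B[2], Ez)
            P = (a * A + b * B) / p
            cc = ca * cb
            sq = np.sqrt(np.pi / p)
            for ia in range(nca):
                ax, ay, az = carts[la, ia]
                for ib in range(ncb):
                    bx, by, bz = carts[lb, ib]
                    sx = Ex[ax, bx, 0] * sq
                    sy = Ey[ay, by, 0] * sq
                    sz = Ez[az, bz, 0] * sq
                    S[ia, ib] += cc * sx * sy * sz
                    # kinetic: 1D pieces
                    tx = (-2.0 * b * b * Ex[ax, bx + 2, 0]
                          + b * (2 * bx + 1) * Ex[ax, bx, 0]) * sq
                    if bx >= 2:
                        tx -= 0.5 * bx * (bx - 1) * Ex[ax, bx - 2, 0] * sq
                    ty = (-2.0 * b * b * Ey[ay, by + 2, 0]
                          + b * (2 * by + 1) * Ey[ay, by, 0]) * sq
                    if by >= 2:
                        ty -= 0.5 * by * (by - 1) * Ey[ay, by - 2, 0] * sq
                    tz = (-2.0 * b * b * Ez[az, bz + 2, 0]
                          + b * (2 * bz + 1) * Ez[az, bz, 0]) * sq
                    if bz >= 2:
                        tz -= 0.5 * bz * (bz - 1) * Ez[az, bz - 2, 0] * sq
                    Tk[ia, ib] += cc * (tx * sy * sz + sx * ty * sz
                                        + sx * sy * tz)
                    # dipole about origin: x = (x - Ax) + (Ax - ox)
                    dx = (Ex[ax + 1, bx, 0] + (A[0] - origin[0])
                          * Ex[ax, bx, 0]) * sq
                    dy = (Ey[ay + 1, by, 0] + (A[1] - origin[1])
                          * Ey[ay, by, 0]) * sq
                    dz = (Ez[az + 1, bz, 0] + (A[2] - origin[2])
                          * Ez[az, bz, 0]) * sq
                    D[0, ia, ib] += cc * dx * sy * sz
                    D[1, ia, ib] += cc * sx * dy * sz
                    D[2, ia, ib] += cc * sx * sy * dz
            # nuclear attraction
            for ic in range(charges.shape[0]):
                hermite_R(Ltot, p, P[0] - centers[ic, 0],
                          P[1] - centers[ic, 1], P[2] - centers[ic, 2], R)
                pref = -charges[ic] * cc * 2.0 * np.pi / p
                for ia in range(nca):
                    ax, ay, az = carts[la, ia]
                    for ib in range(ncb):
                        bx, by, bz = carts[lb, ib]
                        val = 0.0
                        for t in range(ax + bx + 1):
                            for u in range(ay + by + 1):
                                for v in range(az + bz + 1):
                                    val += (Ex[ax, bx, t] * Ey[ay, by, u]
                                            * Ez[az, bz, v] * R[t, u, v])
                        V[ia, ib] += pref * val
    return S, Tk, V, D


# ---------------------------------------------------------------------------
# ERI
# ---------------------------------------------------------------------------
@numba.njit(cache=True)
def eri_quartet(la, lb, lc, ld, A, B, C, Dc,
                ea, ca, eb, cb, ec, cc_, ed, cd, carts):
    """Cartesian (ab|cd) block for one shell quartet."""
    nca = (la + 1) * (la + 2) // 2
    ncb = (lb + 1) * (lb + 2) // 2
    ncc = (lc + 1) * (lc + 2) // 2
    ncd = (ld + 1) * (ld + 2) // 2
    out = np.zeros((nca, ncb, ncc, ncd))
    l1 = la + lb
    l2 = lc + ld
    L = l1 + l2
    E1x = np.zeros((la + 1, lb + 1, l1 + 1))
    E1y = np.zeros((la + 1, lb + 1, l1 + 1))
    E1z = np.zeros((la + 1, lb + 1, l1 + 1))
    E2x = np.zeros((lc + 1, ld + 1, l2 + 1))
    E2y = np.zeros((lc + 1, ld + 1, l2 + 1))
    E2z = np.zeros((lc + 1, ld + 1, l2 + 1))
    R = np.zeros((L + 1, L + 1, L + 1))
    mid = np.zeros((l2 + 1, l2 + 1, l2 + 1, nca, ncb))
    for k1 in range(ea.shape[0]):
        a = ea[k1]
        for k2 in range(eb.shape[0]):
            b = eb[k2]
            p = a + b
            P = (a * A + b * B) / p
            hermite_E(la, lb, a, b, A[0] - B[0], E1x)
            hermite_E(la, lb, a, b, A[1] - B[1], E1y)
            hermite_E(la, lb, a, b, A[2] - B[2], E1z)
            cab = ca[k1] * cb[k2]
            for k3 in range(ec.shape[0]):
                c = ec[k3]
                for k4 in range(ed.shape[0]):
                    d = ed[k4]
                    q = c + d
                    Q = (c * C + d * Dc) / q
                    hermite_E(lc, ld, c, d, C[0] - Dc[0], E2x)
                    hermite_E(lc, ld, c, d, C[1] - Dc[1], E2y)
                    hermite_E(lc, ld, c, d, C[2] - Dc[2], E2z)
                    alpha = p * q / (p + q)
                    hermite_R(L, alpha, P[0] - Q[0], P[1] - Q[1],
                              P[2] - Q[2], R)
                    pref = (cab * cc_[k3] * cd[k4] * 2.0
                            * np.pi ** 2.5
                            / (p * q * np.sqrt(p + q)))
                    # mid[tau,nu,phi, ia,ib] = sum_tuv E1 R[t+tau,...]
                    mid[:, :, :, :, :] = 0.0
                    for ia in range(nca):
                        ax, ay, az = carts[la, ia]
                        for ib in range(ncb):
                            bx, by, bz = carts[lb, ib]
                            for tau in range(l2 + 1):
                                for nu in range(l2 + 1 - tau):
                                    for phi in range(l2 + 1 - tau - nu):
                                        val = 0.0
                                        for t in range(ax + bx + 1):
                                            e1 = E1x[ax, bx, t]
                                            for u in range(ay + by + 1):
                                                e2 = e1 * E1y[ay, by, u]
                                                for v in range(az + bz + 1):
                                                    val += (e2 * E1z[az, bz, v]
                                                            * R[t + tau,
                                                                u + nu,
                                                                v + phi])
                                        mid[tau, nu, phi, ia, ib] = val
                    for icx in range(ncc):
                        cx, cy, cz = carts[lc, icx]
                        for idx in range(ncd):
                            dx, dy, dz = carts[ld, idx]
                            for ia in range(nca):
                                for ib in range(ncb):
                                    val = 0.0
                                    for tau in range(cx + dx + 1):
                                        e1 = E2x[cx, dx, tau]
                                        if tau % 2:
                                            e1 = -e1
                                        for nu in range(cy + dy + 1):
                                            e2 = e1 * E2y[cy, dy, nu]
                                            if nu % 2:
                                                e2 = -e2
                                            for phi in range(cz + dz + 1):
                                                e3 = e2 * E2z[cz, dz, phi]
                                                if phi % 2:
                                                    e3 = -e3
                                                val += (e3 * mid[tau, nu, phi,
                                                                 ia, ib])
                                    out[ia, ib, icx, idx] += pref * val
    return out
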