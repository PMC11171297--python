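"""Numerical determination of the spin-orbital term-list coefficients.

The residual R(t1, t2) = <mu| e^-T H e^T |0> is linear in the unknown term
coefficients, so they follow from an exact least-squares fit against the
brute-force determinant-space residual on random small systems:

* the t1-independent part is fitted from R(0, t2) at random antisymmetric t2;
* the t1-linear part from the complex-step derivative
  Im R(i*h*d1, t2) / h, which is exact to machine precision for the
  polynomial residual.

A fit residual at rounding precision certifies both the completeness of the
candidate list and the rational coefficients.  The shipped coefficients in
``so_terms`` were produced by :func:`fit_coefficients`; the test suite
re-runs the fit on a small instance and compares.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from .. import oracles
from ..mo import MOIntegralSet
from . import engine, so_terms


def _random_moints(n, seed, scale=0.4):
    r = np.random.default_rng(seed)
    h = r.standard_normal((n, n)) * scale
    h = (h + h.T) / 2 + np.diag(np.linspace(0.0, n - 1.0, n))
    A = r.standard_normal((n * n, n * n)) * scale / n
    eri = (A @ A.T).reshape(n, n, n, n)
    for perm in ((1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)):
        eri = (eri + eri.transpose(perm)) / 2
    return MOIntegralSet(h=h, core_energy=0.0, eri=eri)


def _spin(idx, nocc_half, nvirt_half, is_occ):
    half = nocc_half if is_occ else nvirt_half
    return 0 if idx < half else 1


def random_so_amplitudes(n, o, seed, with_t1=True):
    r = np.random.default_rng(seed)
    no, nv = 2 * o, 2 * (n - o)
    t2 = r.standard_normal((no, no, nv, nv)) * 0.3
    t2 = (t2 - t2.transpose(1, 0, 2, 3) - t2.transpose(0, 1, 3, 2)
          + t2.transpose(1, 0, 3, 2)) / 4
    so = np.array([_spin(k, o, 0, True) for k in range(no)])
    sv = np.array([_spin(k, 0, n - o, False) for k in range(nv)])
    ok = (so[:, None, None, None] + so[None, :, None, None]
          == sv[None, None, :, None] + sv[None, None, None, :])
    t2 *= ok
    t1 = None
    if with_t1:
        t1 = r.standard_normal((no, nv)) * 0.3
        t1 *= (so[:, None] == sv[None, :])
    return t1, t2


def oracle_residual(moints, o, t1, t2):
    """Determinant-space <mu|e^-T H e^T|0> as so residual tensors."""
    n = moints.n
    space = oracles.DeterminantSpace(n, 2 * o, "all")
    H = oracles.build_dense_hamiltonian(moints, space)
    occ_so, virt_so = oracles.so_index_maps(n, o)
    T = oracles.so_cluster_matrix(space, occ_so, virt_so, t1, t2)
    e0 = np.zeros(space.dim, dtype=complex if (t1 is not None and
                  np.iscomplexobj(t1)) or np.iscomplexobj(t2) else float)
    e0[space.hf_index()] = 1.0
    w = oracles.apply_exp(-T, H @ oracles.apply_exp(T, e0))
    return oracles.so_projection_tensors(space, occ_so, virt_so, w)


def _design_matrix(candidates, out, store, out_shape):
    cols = []
    for factors in candidates:
        cols.append(engine.evaluate([(1.0, out, factors)], store,
                                    out_shape).ravel())
    return np.array(cols).T


def fit_coefficients(instances=((4, 2, 0), (5, 2, 1), (4, 2, 2), (5, 3, 3)),
                     rationalize=True, verbose=False):
    """Fit all term coefficients; returns (singles, doubles) lists."""
    rows_src = {"S": ([], []), "D": ([], [])}
    rows_lin = {"S": ([], []), "D": ([], [])}
    hstep = 1e-7

    for (n, o, seed) in instances:
        mi = _random_moints(n, seed)
        f_so, v_so, _ = oracles.spinorb_tensors(mi, o)
        no, nv = 2 * o, 2 * (n - o)
        t1, t2 = random_so_amplitudes(n, o, seed + 100)

        # --- source part: t1 = 0
        R1, R2 = oracle_residual(mi, o, None, t2)
        store = engine.TensorStore(no, nv, full={"f": f_so, "v": v_so},
                                   plain={"t1": np.zeros((no, nv)), "t2": t2})
        nt1 = [c for c in so_terms.SINGLES_CANDIDATES
               if not any(nm == "t1" for nm, _ in c)]
        nt1d = [c for c in so_terms.DOUBLES_CANDIDATES
                if not any(nm == "t1" for nm, _ in c)]
        rows_src["S"][0].append(_design_matrix(nt1, "ia", store, R1.shape))
        rows_src["S"][1].append(R1.ravel())
        rows_src["D"][0].append(_design_matrix(nt1d, "ijab", store, R2.shape))
        rows_src["D"][1].append(R2.ravel())

        # --- t1-linear part: complex step along random d1
        d1 = t1
        R1c, R2c = oracle_residual(mi, o, 1j * hstep * d1, t2.astype(complex))
        dR1 = np.imag(R1c) / hstep
        dR2 = np.imag(R2c) / hstep
        store1 = engine.TensorStore(no, nv, full={"f": f_so, "v": v_so},
                                    plain={"t1": d1, "t2": t2})
        yt1 = [c for c in so_terms.SINGLES_CANDIDATES
               if any(nm == "t1" for nm, _ in c)]
        yt1d = [c for c in so_terms.DOUBLES_CANDIDATES
                if any(nm == "t1" for nm, _ in c)]
        rows_lin["S"][0].append(_design_matrix(yt1, "ia", store1, R1.shape))
        rows_lin["S"][1].append(dR1.ravel())
        rows_lin["D"][0].append(_design_matrix(yt1d, "ijab", store1, R2.shape))
        rows_lin["D"][1].append(dR2.ravel())

    def solve(rows):
        A = np.vstack(rows[0])
        b = np.concatenate(rows[1])
        c, *_ = np.linalg.lstsq(A, b, rcond=None)
        resid = np.abs(A @ c - b).max()
        return c, resid

    out = {}
    for key in ("S", "D"):
        c_src, r1 = solve(rows_src[key])
        c_lin, r2 = solve(rows_lin[key])
        if max(r1, r2) > 1e-6:
            raise RuntimeError(
                f"candidate basis incomplete for {key}: fit residuals "
                f"{r1:.2e}, {r2:.2e}")
        out[key] = (c_src, c_lin, max(r1, r2))
        if verbose:
            print(key, "fit residuals", r1, r2)

    def assemble(cands, c_src, c_lin):
        coeffs = []
        isrc = ilin = 0
        for cand in cands:
            if any(nm == "t1" for nm, _ in cand):
                val = c_lin[ilin]
                ilin += 1
            else:
                val = c_src[isrc]
                isrc += 1
            if rationalize:
                fr = Fraction(val).limit_denominator(8)
                if abs(float(fr) - val) > 1e-6:
                    raise RuntimeError(
                        f"coefficient {val} of {cand} not a small rational")
                val = float(fr)
            if abs(val) < 1e-10:
                val = 0.0
            coeffs.append(val)
        return coeffs

    singles = assemble(so_terms.SINGLES_CANDIDATES, *out["S"][:2])
    doubles = assemble(so_terms.DOUBLES_CANDIDATES, *out["D"][:2])
    return singles, doubles
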