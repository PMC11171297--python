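"""Generate the shipped correlation-consistent basis files.

Exponents are the published Dunning (aug-)cc-pVnZ values; the general
contraction coefficients are regenerated here as spherically averaged
atomic Hartree-Fock orbitals in the uncontracted primitive basis (the
construction that defines those contractions).  For one-electron atoms the
"HF" orbital is the core-Hamiltonian eigenvector.  Shells whose atomic
occupation is zero (e.g. Li p) are left uncontracted.

Run from the repository root:  python scripts/make_cc_basis.py
"""

from __future__ import annotations

import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from paircc.integrals import ao, basis  # noqa: E402
from paircc.molecule import Molecule  # noqa: E402

OUT = pathlib.Path(__file__).resolve().parents[1] / "src/paircc/data/basis"


# ---------------------------------------------------------------------------
# spherically averaged atomic HF in an uncontracted basis
# ---------------------------------------------------------------------------
def atomic_hf(element, prim_exps, occupations, maxiter=200, tol=1e-10):
    """occupations: dict l -> list of per-orbital electron counts (summed
    over the 2l+1 components), e.g. F: {0: [2, 2], 1: [5]}.
    Returns dict l -> (radial coefficient matrix, columns = occupied AOs)."""
    mol = Molecule([element], np.zeros((1, 3)))
    bdict = {element: [(l, np.array([e]), np.array([1.0]))
                       for l, exps in prim_exps.items() for e in exps]}
    aoints = ao.build_from_backend(mol, bdict)
    S, h = aoints.overlap, aoints.core_hamiltonian
    n = aoints.n_basis
    # AO index bookkeeping: for each l, radial index r, m -> AO column
    ao_idx = {}
    pos = 0
    for l, exps in prim_exps.items():
        for r in range(len(exps)):
            for mi in range(2 * l + 1):
                ao_idx.setdefault((l, mi), []).append(pos)
                pos += 1
    assert pos == n

    import scipy.linalg

    nelec = sum(sum(v) for v in occupations.values())
    coeffs = {}
    if nelec == 1:
        (l,) = [l for l, v in occupations.items() if sum(v)]
        idx = np.array(ao_idx[(l, 0)])
        w, V = scipy.linalg.eigh(h[np.ix_(idx, idx)], S[np.ix_(idx, idx)])
        coeffs[l] = V[:, :1]
        return coeffs, float(w[0])

    D = np.zeros((n, n))
    E = E_old = np.inf
    for it in range(maxiter):
        J = np.einsum("pqrs,rs->pq", aoints.eri, D, optimize=True)
        K = np.einsum("prqs,rs->pq", aoints.eri, D, optimize=True)
        F = h + J - 0.5 * K
        E = 0.5 * np.einsum("pq,pq->", D, h + F)
        Dnew = np.zeros((n, n))
        coeffs = {}
        for l, occs in occupations.items():
            idx0 = np.array(ao_idx[(l, 0)])
            w, V = scipy.linalg.eigh(F[np.ix_(idx0, idx0)],
                                     S[np.ix_(idx0, idx0)])
            coeffs[l] = V[:, :len(occs)]
            for k, occ in enumerate(occs):
                frac = occ / (2 * l + 1)
                for mi in range(2 * l + 1):
                    idx = np.array(ao_idx[(l, mi)])
                    c = np.zeros(n)
                    c[idx] = V[:, k]
                    Dnew += frac * np.outer(c, c)
        if abs(E - E_old) < tol and it > 10:
            break
        E_old = E
        D = 0.5 * (D + Dnew) if it < 8 else Dnew
    return coeffs, float(E)


# ---------------------------------------------------------------------------
# basis definitions: published exponents + contraction scheme
# ---------------------------------------------------------------------------
CC_PVDZ = {
    "H": dict(exps={0: [13.01, 1.962, 0.4446, 0.1220], 1: [0.727]},
              occ={0: [1]}, free={0: [0.1220], 1: [0.727]}),
    "He": dict(exps={0: [38.36, 5.770, 1.240, 0.2976], 1: [1.275]},
               occ={0: [2]}, free={0: [0.2976], 1: [1.275]}),
    "Li": dict(exps={0: [1469.0, 220.5, 50.26, 14.24, 4.581, 1.580, 0.564,
                         0.07345, 0.02805],
                     1: [1.534, 0.2749, 0.07362, 0.02403], 2: [0.1239]},
               occ={0: [2, 1]},
               free={0: [0.02805], 1: [1.534, 0.2749, 0.07362, 0.02403],
                     2: [0.1239]}),
    "C": dict(exps={0: [6665.0, 1000.0, 228.0, 64.71, 21.06, 6.459, 2.525,
                        0.5215, 0.1596],
                    1: [9.439, 2.002, 0.5456, 0.1517], 2: [0.550]},
              occ={0: [2, 2], 1: [2]},
              free={0: [0.1596], 1: [0.1517], 2: [0.550]}),
    "N": dict(exps={0: [9046.0, 1357.0, 309.3, 87.73, 28.56, 10.21, 3.838,
                        0.7466, 0.2248],
                    1: [13.55, 2.917, 0.7973, 0.2185], 2: [0.817]},
              occ={0: [2, 2], 1: [3]},
              free={0: [0.2248], 1: [0.2185], 2: [0.817]}),
    "O": dict(exps={0: [11720.0, 1759.0, 400.8, 113.7, 37.03, 13.27, 5.025,
                        1.013, 0.3023],
                    1: [17.70, 3.854, 1.046, 0.2753], 2: [1.185]},
              occ={0: [2, 2], 1: [4]},
              free={0: [0.3023], 1: [0.2753], 2: [1.185]}),
    "F": dict(exps={0: [14710.0, 2207.0, 502.8, 140.6, 46.97, 17.35, 6.870,
                        1.750, 0.3669],
                    1: [22.67, 4.977, 1.347, 0.3471], 2: [1.640]},
              occ={0: [2, 2], 1: [5]},
              free={0: [0.3669], 1: [0.3471], 2: [1.640]}),
}

AUG_CC_PVTZ = {
    "H": dict(exps={0: [33.87, 5.095, 1.159, 0.3258, 0.1027],
                    1: [1.407, 0.388], 2: [1.057]},
              occ={0: [1]},
              free={0: [0.3258, 0.1027, 0.02526],
                    1: [1.407, 0.388, 0.102], 2: [1.057, 0.247]},
              diffuse={0: [0.02526], 1: [0.102], 2: [0.247]}),
    "F": dict(exps={0: [19500.0, 2923.0, 664.5, 187.5, 60.62, 21.42, 7.950,
                        2.257, 0.8815, 0.2857],
                    1: [43.88, 9.926, 2.930, 0.9132, 0.2672],
                    2: [3.107, 0.855], 3: [1.917]},
              occ={0: [2, 2], 1: [5]},
              free={0: [0.8815, 0.2857, 0.1076],
                    1: [0.9132, 0.2672, 0.07361],
                    2: [3.107, 0.855, 0.292], 3: [1.917, 0.724]},
              diffuse={0: [0.1076], 1: [0.07361], 2: [0.292], 3: [0.724]}),
}

LSYM = "spdf"


def emit(name, table, header):
    lines = [f"# {header}",
             "# Exponents: published Dunning correlation-consistent values.",
             "# General-contraction coefficients regenerated by spherically",
             "# averaged atomic HF in the uncontracted primitive basis",
             "# (scripts/make_cc_basis.py)."]
    for el, spec in table.items():
        exps = {l: list(v) for l, v in spec["exps"].items()}
        for l, dif in spec.get("diffuse", {}).items():
            for e in dif:
                if e not in exps.get(l, []):
                    exps.setdefault(l, []).append(e)
        coeffs, E = atomic_hf(el, {l: v for l, v in spec["exps"].items()},
                              spec["occ"])
        print(f"{name} {el}: atomic SCF E = {E}")
        for l in sorted(exps):
            occ_cols = coeffs.get(l)
            n_contracted = len(spec["occ"].get(l, []))
            if n_contracted and occ_cols is not None:
                prim = spec["exps"][l]
                lines.append(f"{el} {LSYM[l]}")
                for i, e in enumerate(prim):
                    row = f"  {e:>14.6f}"
                    for k in range(n_contracted):
                        row += f"  {occ_cols[i, k]: .10f}"
                    lines.append(row)
            for e in spec["free"].get(l, []):
                lines.append(f"{el} {LSYM[l]}")
                lines.append(f"  {e:>14.6f}   1.0")
    path = OUT / f"{name}.nwbas"
    path.write_text("\n".join(lines) + "\n")
    print("wrote", path)


if __name__ == "__main__":
    emit("cc-pvdz", CC_PVDZ, "cc-pVDZ-style correlation-consistent basis")
    emit("aug-cc-pvtz", AUG_CC_PVTZ,
         "aug-cc-pVTZ-style correlation-consistent basis")
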