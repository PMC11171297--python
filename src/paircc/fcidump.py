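"""FCIDUMP reading and writing.

Dialect: 1-based orbital indices, real orbitals, 8-fold permutational
symmetry implied, no point-group labels (ISYM ignored on read, written as 1).
The scalar record with all-zero indices is the core energy.  One-electron
integrals carry two zero ket indices.
"""

from __future__ import annotations

import re

import numpy as np

from .mo import MOIntegralSet


def read_fcidump(path) -> tuple[MOIntegralSet, int]:
    """Parse an FCIDUMP file; returns (MOIntegralSet, nelec).

    Absent entries are zero.  Malformed headers or out-of-range indices
    raise ValueError naming the offending line.
    """
    with open(path) as fh:
        text = fh.read()
    m = re.search(r"NORB\s*=\s*(\d+)", text, re.I)
    ne = re.search(r"NELEC\s*=\s*(\d+)", text, re.I)
    if not m or not ne:
        raise ValueError(f"{path}: malformed FCIDUMP header (need NORB, NELEC)")
    norb, nelec = int(m.group(1)), int(ne.group(1))
    end = re.search(r"^\s*(/|&END|\$END)\s*$", text, re.I | re.M)
    if not end:
        raise ValueError(f"{path}: unterminated FCIDUMP namelist header")
    body = text[end.end():].lstrip("\n")

    h = np.zeros((norb, norb))
    eri = np.zeros((norb, norb, norb, norb))
    core = 0.0
    for lineno, line in enumerate(body.splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 5:
            raise ValueError(f"{path}: bad record on data line {lineno}")
        val = float(parts[0])
        i, j, k, l = (int(x) for x in parts[1:])
        if max(i, j, k, l) > norb or min(i, j, k, l) < 0:
            raise ValueError(f"{path}: index out of range on data line {lineno}")
        if i == 0:
            core = val
        elif k == 0:
            if j == 0:
                raise ValueError(f"{path}: bad index pattern on data line {lineno}")
            h[i - 1, j - 1] = h[j - 1, i - 1] = val
        else:
            for (p, q, r, s) in _perms(i - 1, j - 1, k - 1, l - 1):
                eri[p, q, r, s] = val
    return MOIntegralSet(h=h, core_energy=core, eri=eri), nelec


def _perms(i, j, k, l):
    return {(i, j, k, l), (j, i, k, l), (i, j, l, k), (j, i, l, k),
            (k, l, i, j), (l, k, i, j), (k, l, j, i), (l, k, j, i)}


def write_fcidump(moints: MOIntegralSet, nelec: int, path,
                  thresh: float = 1e-16) -> None:
    """Emit symmetry-unique entries with |value| > thresh; round-trip safe."""
    n = moints.n
    h = moints.h
    if np.abs(h - h.T).max() > 1e-10:
        raise ValueError("one-electron matrix is not symmetric")
    eri = moints.eri_dense()
    for perm in ((1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)):
        if np.abs(eri - eri.transpose(perm)).max() > 1e-10:
            raise ValueError("two-electron tensor lacks 8-fold symmetry")
    with open(path, "w") as fh:
        fh.write(f"&FCI NORB={n},NELEC={nelec},MS2=0,\n")
        fh.write("ORBSYM=" + "1," * n + "\n")
        fh.write("ISYM=1,\n/\n")
        for i in range(n):
            for j in range(i + 1):
                for k in range(i + 1):
                    lmax = j if k == i else k
                    for l in range(lmax + 1):
                        v = eri[i, j, k, l]
                        if abs(v) > thresh:
                            fh.write(f" {v:23.16e} {i+1:4d} {j+1:4d} {k+1:4d} {l+1:4d}\n")
        for i in range(n):
            for j in range(i + 1):
                if abs(h[i, j]) > thresh:
                    fh.write(f" {h[i, j]:23.16e} {i+1:4d} {j+1:4d}    0    0\n")
        fh.write(f" {moints.core_energy:23.16e}    0    0    0    0\n")
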