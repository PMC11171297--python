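"""Gaussian basis sets: NWChem-format text parsing, shell construction,
and Cartesian -> real-spherical-harmonic transformation matrices.

Shipped basis files live in ``paircc/data/basis`` (plain text).  Primitive
coefficients in the files refer to normalized primitives of the pure-l
(x^l) convention; contracted functions are renormalized on load.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np

L_SYMBOLS = {"s": 0, "p": 1, "d": 2, "f": 3, "g": 4}
_DF = {-1: 1.0, 0: 1.0}  # double factorials (n)!!
for _n in range(1, 30):
    _DF[_n] = _n * _DF[_n - 2]


def double_factorial(n):
    return _DF[n]


def cartesian_components(l):
    """Lexicographic (lx, ly, lz) with lx descending."""
    return [(lx, ly, l - lx - ly)
            for lx in range(l, -1, -1) for ly in range(l - lx, -1, -1)]


def n_cart(l):
    return (l + 1) * (l + 2) // 2


# ---------------------------------------------------------------------------
# real solid harmonics and the cart->spherical matrices
# ---------------------------------------------------------------------------
def _real_solid_harmonics(l):
    """Polynomials (monomial dicts) for the real solid harmonics r^l Y_lm,
    m = -l..l, up to m-independent normalization (fixed numerically)."""
    x, y, z = (1, 0, 0), (0, 1, 0), (0, 0, 1)
    if l == 0:
        return [{(0, 0, 0): 1.0}]
    if l == 1:
        return [{y: 1.0}, {z: 1.0}, {x: 1.0}]
    if l == 2:
        return [
            {(1, 1, 0): 1.0},                                   # xy
            {(0, 1, 1): 1.0},                                   # yz
            {(0, 0, 2): 1.0, (2, 0, 0): -0.5, (0, 2, 0): -0.5},  # 3z^2-r^2
            {(1, 0, 1): 1.0},                                   # xz
            {(2, 0, 0): 1.0, (0, 2, 0): -1.0},                  # x^2-y^2
        ]
    if l == 3:
        return [
            {(2, 1, 0): 3.0, (0, 3, 0): -1.0},                  # y(3x^2-y^2)
            {(1, 1, 1): 1.0},                                   # xyz
            {(0, 1, 2): 4.0, (2, 1, 0): -1.0, (0, 3, 0): -1.0},  # y(5z^2-r^2)
            {(0, 0, 3): 2.0, (2, 0, 1): -3.0, (0, 2, 1): -3.0},  # z(5z^2-3r^2)
            {(1, 0, 2): 4.0, (3, 0, 0): -1.0, (1, 2, 0): -1.0},  # x(5z^2-r^2)
            {(2, 0, 1): 1.0, (0, 2, 1): -1.0},                  # z(x^2-y^2)
            {(3, 0, 0): 1.0, (1, 2, 0): -3.0},                  # x(x^2-3y^2)
        ]
    raise NotImplementedError(f"l = {l} not supported")


def cart_to_spherical(l):
    """(2l+1) x ncart matrix acting on the engine's Cartesian components
    (which carry the x^l primitive normalization)."""
    carts = cartesian_components(l)
    nc = len(carts)
    dfl = double_factorial(2 * l - 1)
    metric = np.zeros((nc, nc))
    for i, (a1, b1, c1) in enumerate(carts):
        for j, (a2, b2, c2) in enumerate(carts):
            if (a1 + a2) % 2 or (b1 + b2) % 2 or (c1 + c2) % 2:
                continue
            metric[i, j] = (double_factorial(a1 + a2 - 1)
                            * double_factorial(b1 + b2 - 1)
                            * double_factorial(c1 + c2 - 1)) / dfl
    T = np.zeros((2 * l + 1, nc))
    for m, poly in enumerate(_real_solid_harmonics(l)):
        row = np.zeros(nc)
        for mono, coef in poly.items():
            row[carts.index(mono)] = coef
        T[m] = row / np.sqrt(row @ metric @ row)
    return T


C2S = {l: cart_to_spherical(l) for l in range(4)}


# ---------------------------------------------------------------------------
# shells
# ---------------------------------------------------------------------------
@dataclass
class Shell:
    l: int
    center: np.ndarray
    exps: np.ndarray
    coefs: np.ndarray           # includes primitive norms; contracted-normalized
    atom_index: int

    @property
    def n_sph(self):
        return 2 * self.l + 1

    @property
    def n_cart(self):
        return n_cart(self.l)


def _primitive_norm(alpha, l):
    return ((2 * alpha / np.pi) ** 0.75
            * (4 * alpha) ** (l / 2.0)
            / np.sqrt(double_factorial(2 * l - 1)))


def make_shell(l, center, exps, coefs, atom_index=0):
    exps = np.asarray(exps, float)
    coefs = np.asarray(coefs, float) * _primitive_norm(exps, l)
    # renormalize the contracted x^l-type function
    p = exps[:, None] + exps[None, :]
    s = (np.pi / p) ** 1.5 * double_factorial(2 * l - 1) / (2 * p) ** l
    norm2 = coefs @ s @ coefs
    coefs = coefs / np.sqrt(norm2)
    return Shell(l=l, center=np.asarray(center, float), exps=exps,
                 coefs=coefs, atom_index=atom_index)


# ---------------------------------------------------------------------------
# basis file parsing (NWChem-like format)
# ---------------------------------------------------------------------------
def parse_basis_text(text):
    """element -> list of (l, exps, coefs); general contractions expanded
    into one segmented shell per column."""
    def is_number_row(ln):
        s = ln.strip()
        return bool(s) and (s[0].isdigit() or s[0] in ".-+")

    basis = {}
    lines = [ln.split("#")[0].rstrip() for ln in text.splitlines()]
    i = 0
    while i < len(lines):
        ln = lines[i].strip()
        i += 1
        if not ln or ln.lower().startswith(("basis", "end")):
            continue
        parts = ln.split()
        if len(parts) == 2 and parts[1].lower() in L_SYMBOLS:
            elem, lsym = parts[0], parts[1].lower()
            rows = []
            while i < len(lines) and is_number_row(lines[i]):
                rows.append([float(x.replace("D", "E").replace("d", "e"))
                             for x in lines[i].split()])
                i += 1
            rows = np.array(rows)
            exps = rows[:, 0]
            for col in range(1, rows.shape[1]):
                coefs = rows[:, col]
                mask = np.abs(coefs) > 0
                basis.setdefault(elem, []).append(
                    (L_SYMBOLS[lsym], exps[mask], coefs[mask]))
        else:
            raise ValueError(f"cannot parse basis line: {ln!r}")
    return basis


def load_basis(name):
    """Load a shipped basis set by name (case-insensitive)."""
    fname = name.lower().replace("*", "s") + ".nwbas"
    root = importlib.resources.files("paircc.data") / "basis" / fname
    try:
        text = root.read_text()
    except FileNotFoundError as exc:
        raise ValueError(f"unknown basis set {name!r} (no file {fname})") from exc
    return parse_basis_text(text)


def build_shells(molecule, basis_name_or_dict):
    if isinstance(basis_name_or_dict, str):
        basis = load_basis(basis_name_or_dict)
    else:
        basis = basis_name_or_dict
    shells = []
    for ia, el in enumerate(molecule.elements):
        if el not in basis:
            raise ValueError(f"basis has no element {el}")
        for (l, exps, coefs) in basis[el]:
            shells.append(make_shell(l, molecule.coords[ia], exps, coefs, ia))
    return shells


def ao_labels(shells):
    labels = []
    for s in shells:
        for m in range(-s.l, s.l + 1):
            labels.append((s.atom_index, s.l, m))
    return labels


def atom_ao_map(shells):
    """AO index -> atom index (spherical AO ordering)."""
    out = []
    for s in shells:
        out.extend([s.atom_index] * s.n_sph)
    return np.array(out, dtype=int)
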