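"""Molecular geometry container and XYZ I/O.

Coordinates are stored in bohr.  XYZ files follow the usual convention of
Angstrom, element symbol first.  Only closed-shell (singlet) species are
supported: the pair-coupled-cluster framework used throughout this package
is restricted to molecules with singlet ground states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import angstrom_to_bohr, bohr_to_angstrom

ELEMENT_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}

# Number of electrons in the noble-gas core, used by the frozen-core
# ("nonvalence") rule: He core for Li-Ne, Ne core for Na-Ar.
_CORE_ELECTRONS = {z: (0 if z <= 2 else 2 if z <= 10 else 10) for z in range(1, 19)}


@dataclass
class Molecule:
    """A molecule: element symbols, nuclear charges, coordinates in bohr."""

    elements: list[str]
    coords: np.ndarray          # (natom, 3), bohr
    charge: int = 0
    multiplicity: int = 1

    nuclear_charges: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.multiplicity != 1:
            raise ValueError("only singlet (multiplicity 1) molecules are supported")
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        try:
            self.nuclear_charges = np.array(
                [ELEMENT_NUMBERS[e] for e in self.elements], dtype=float
            )
        except KeyError as exc:  # pragma: no cover - configuration error path
            raise ValueError(f"unknown element symbol: {exc}") from exc
        if len(self.elements) != len(self.coords):
            raise ValueError("elements and coords length mismatch")

    # ------------------------------------------------------------------
    @property
    def natom(self) -> int:
        return len(self.elements)

    @property
    def n_electrons(self) -> int:
        return int(self.nuclear_charges.sum()) - self.charge

    def n_frozen_core_orbitals(self) -> int:
        """Doubly occupied nonvalence orbitals under the noble-gas-core rule."""
        ncore_el = sum(_CORE_ELECTRONS[ELEMENT_NUMBERS[e]] for e in self.elements)
        return ncore_el // 2

    def nuclear_repulsion(self) -> float:
        e = 0.0
        for i in range(self.natom):
            for j in range(i):
                r = np.linalg.norm(self.coords[i] - self.coords[j])
                e += self.nuclear_charges[i] * self.nuclear_charges[j] / r
        return e

    def nuclear_dipole(self, origin=None) -> np.ndarray:
        """Nuclear dipole sum_i Z_i (R_i - origin), atomic units."""
        origin = np.zeros(3) if origin is None else np.asarray(origin, float)
        return np.einsum("i,ix->x", self.nuclear_charges, self.coords - origin)

    # ------------------------------------------------------------------
    @classmethod
    def diatomic(cls, element_a: str, element_b: str, r_angstrom: float,
                 charge: int = 0) -> "Molecule":
        """A--B with A at the origin and B on the positive z axis.

        By the scan convention, A is the less electronegative atom, so a
        positive mu_z indicates A(-)B(+) polarity and a negative mu_z
        indicates A(+)B(-).
        """
        r = angstrom_to_bohr(r_angstrom)
        return cls([element_a, element_b],
                   np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r]]), charge=charge)

    @classmethod
    def from_xyz(cls, path, charge: int = 0) -> "Molecule":
        with open(path) as fh:
            lines = fh.read().splitlines()
        nat = int(lines[0].split()[0])
        elements, coords = [], []
        for ln in lines[2:2 + nat]:
            parts = ln.split()
            elements.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        return cls(elements, angstrom_to_bohr(np.array(coords)), charge=charge)

    def to_xyz(self, path, comment: str = "") -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.natom}\n{comment}\n")
            for el, xyz in zip(self.elements, bohr_to_angstrom(self.coords)):
                fh.write(f"{el} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}\n")
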