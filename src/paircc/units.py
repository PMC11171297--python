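"""Unit conversions.

All internal quantities are in Hartree atomic units.  User-facing geometry
I/O is in Angstrom and dipole reporting is in Debye; the two constants below
are the only places where those conversions live.
"""

# CODATA 2010, matching common quantum-chemistry package conventions.
ANGSTROM_PER_BOHR = 0.52917721092
BOHR_PER_ANGSTROM = 1.0 / ANGSTROM_PER_BOHR

# 1 atomic unit of electric dipole moment (e * a0) in Debye.
DEBYE_PER_AU = 2.5417464519


def bohr_to_angstrom(x):
    return x * ANGSTROM_PER_BOHR


def angstrom_to_bohr(x):
    return x * BOHR_PER_ANGSTROM


def au_to_debye(mu):
    return mu * DEBYE_PER_AU


def debye_to_au(mu):
    return mu / DEBYE_PER_AU
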