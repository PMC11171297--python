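import numpy as np
import pytest

from paircc import oracles
from paircc.integrals.ao import build_from_backend
from paircc.mo import MOIntegralSet, transform_to_mo
from paircc.molecule import Molecule
from paircc.scf import solve_rhf


def random_moints(n, seed, scale=0.35):
    """Random symmetric 'molecular' integrals with a PSD two-electron part."""
    r = np.random.default_rng(seed)
    h = r.standard_normal((n, n)) * scale
    h = (h + h.T) / 2 + np.diag(np.linspace(0.0, n - 1.0, n))
    A = r.standard_normal((n * n, n * n)) * scale / n
    eri = (A @ A.T).reshape(n, n, n, n)
    for perm in ((1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)):
        eri = (eri + eri.transpose(perm)) / 2
    return MOIntegralSet(h=h, core_energy=0.31, eri=eri)


@pytest.fixture(scope="session")
def h2_sto3g():
    mol = Molecule.diatomic("H", "H", 0.74085)  # 1.4 bohr
    ao = build_from_backend(mol, "sto-3g")
    scf = solve_rhf(ao, 2)
    return mol, ao, scf, transform_to_mo(ao, scf.mocoeffs.C)


@pytest.fixture(scope="session")
def lih_sto3g():
    mol = Molecule.diatomic("Li", "H", 1.5957)
    ao = build_from_backend(mol, "sto-3g")
    scf = solve_rhf(ao, 4)
    return mol, ao, scf, transform_to_mo(ao, scf.mocoeffs.C)


@pytest.fixture(scope="session")
def heh_plus_sto3g():
    mol = Molecule.diatomic("H", "He", 0.7743, charge=1)
    ao = build_from_backend(mol, "sto-3g")
    scf = solve_rhf(ao, 2)
    return mol, ao, scf, transform_to_mo(ao, scf.mocoeffs.C)


@pytest.fixture(scope="session")
def pairing_2x4():
    """Two pairs in four nondegenerate levels, moderate coupling."""
    return oracles.make_pairing_hamiltonian([0.0, 1.0, 2.2, 3.1], G=0.35)
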