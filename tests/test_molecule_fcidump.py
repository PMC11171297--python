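import numpy as np
import pytest

from paircc import oracles
from paircc.fcidump import read_fcidump, write_fcidump
from paircc.mo import MOIntegralSet
from paircc.molecule import Molecule
from paircc.units import angstrom_to_bohr


class TestMolecule:
    def test_diatomic_convention(self):
        mol = Molecule.diatomic("H", "F", 0.917)
        assert mol.elements == ["H", "F"]
        np.testing.assert_allclose(mol.coords[0], 0.0)
        assert mol.coords[1, 2] == pytest.approx(angstrom_to_bohr(0.917))
        assert mol.coords[1, :2] == pytest.approx([0.0, 0.0])

    def test_nuclear_repulsion_closed_form(self):
        r = 1.0977
        mol = Molecule.diatomic("N", "N", r)
        assert mol.nuclear_repulsion() == pytest.approx(
            49.0 / angstrom_to_bohr(r), rel=1e-12)

    def test_only_singlets(self):
        with pytest.raises(ValueError):
            Molecule(["H"], np.zeros((1, 3)), multiplicity=2)

    def test_frozen_core_rule(self):
        # He core for Li-Ne, none for H/He
        assert Molecule.diatomic("H", "F", 1.0).n_frozen_core_orbitals() == 1
        assert Molecule.diatomic("Li", "H", 1.6).n_frozen_core_orbitals() == 1
        assert Molecule.diatomic("H", "H", 0.7).n_frozen_core_orbitals() == 0
        assert Molecule(["Na", "Cl"], np.array([[0, 0, 0], [0, 0, 4.0]])
                        ).n_frozen_core_orbitals() == 10

    def test_xyz_roundtrip(self, tmp_path):
        mol = Molecule.diatomic("Li", "H", 1.5957)
        p = tmp_path / "m.xyz"
        mol.to_xyz(p)
        mol2 = Molecule.from_xyz(p)
        np.testing.assert_allclose(mol2.coords, mol.coords, atol=1e-9)
        assert mol2.elements == mol.elements


class TestFCIDump:
    def test_roundtrip_lossless(self, tmp_path, pairing_2x4):
        path = tmp_path / "pair.fcidump"
        write_fcidump(pairing_2x4, 4, path)
        mi, nelec = read_fcidump(path)
        assert nelec == 4
        np.testing.assert_allclose(mi.h, pairing_2x4.h, atol=1e-12)
        np.testing.assert_allclose(mi.eri, pairing_2x4.eri, atol=1e-12)
        assert mi.core_energy == pytest.approx(pairing_2x4.core_energy,
                                               abs=1e-12)

    def test_fci_invariant_under_roundtrip(self, tmp_path, pairing_2x4):
        path = tmp_path / "pair.fcidump"
        write_fcidump(pairing_2x4, 4, path)
        mi, nelec = read_fcidump(path)
        e0 = oracles.dense_fci(pairing_2x4, 4).energy
        e1 = oracles.dense_fci(mi, 4).energy
        assert e1 == pytest.approx(e0, abs=1e-12)

    def test_one_electron_only_file(self, tmp_path):
        path = tmp_path / "h_only.fcidump"
        mi0 = MOIntegralSet(h=np.diag([0.5, 1.5]), core_energy=0.25,
                            eri=np.zeros((2, 2, 2, 2)))
        write_fcidump(mi0, 2, path)
        text = path.read_text()
        # zero two-electron block: no 4-index records at all
        for line in text.splitlines():
            parts = line.split()
            if len(parts) == 5 and parts[3] != "0":
                pytest.fail(f"unexpected 4-index record: {line}")
        mi, _ = read_fcidump(path)
        assert np.all(mi.eri == 0.0)
        assert mi.core_energy == 0.25

    def test_header_and_errors(self, tmp_path):
        bad = tmp_path / "bad.fcidump"
        bad.write_text("&FCI NELEC=2\n/\n")
        with pytest.raises(ValueError, match="NORB"):
            read_fcidump(bad)
        bad.write_text("&FCI NORB=2,NELEC=2\n/\n 1.0 5 1 1 1\n")
        with pytest.raises(ValueError, match="line 1"):
            read_fcidump(bad)

    def test_shipped_h2_fixture(self):
        import pathlib
        path = pathlib.Path(__file__).parent / "fixtures/h2_sto3g.fcidump"
        mi, nelec = read_fcidump(path)
        assert mi.n == 2 and nelec == 2
        # the scalar record is the core (here: nuclear repulsion) energy
        assert mi.core_energy == pytest.approx(1.0 / 1.4000, abs=2e-4)
        e = oracles.dense_fci(mi, 2).energy
        assert e == pytest.approx(-1.137276, abs=1e-5)

    def test_asymmetric_input_rejected(self, tmp_path):
        h = np.array([[0.0, 0.3], [0.1, 1.0]])
        mi = MOIntegralSet(h=h, eri=np.zeros((2, 2, 2, 2)))
        with pytest.raises(ValueError, match="symmetric"):
            write_fcidump(mi, 2, tmp_path / "x.fcidump")


class TestHDF5State:
    def test_amplitude_roundtrip(self, tmp_path, pairing_2x4):
        from paircc import pccd
        from paircc.io_hdf5 import load_state, save_state
        res = pccd.solve_pccd(pairing_2x4, 2)
        lam = pccd.solve_pccd_lambda(res.t.t, pairing_2x4, 2)
        path = tmp_path / "state.h5"
        save_state(path, tp=res.t.t, lam_p=lam.lam, E_corr=res.E_corr)
        back = load_state(path)
        np.testing.assert_array_equal(back["tp"], res.t.t)
        np.testing.assert_array_equal(back["lam_p"], lam.lam)
        assert back["E_corr"] == res.E_corr
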