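"""HDF5 export/import of amplitudes, densities and restart orbitals."""

from __future__ import annotations

import h5py
import numpy as np


def save_state(path, **arrays):
    """Save named arrays (amplitudes, RDMs, orbital rotations) with index
    metadata; scalars are stored as attributes."""
    with h5py.File(path, "w") as fh:
        for name, val in arrays.items():
            if val is None:
                continue
            if np.isscalar(val):
                fh.attrs[name] = val
            else:
                ds = fh.create_dataset(name, data=np.asarray(val))
                ds.attrs["axes"] = _axes_hint(name, np.asarray(val).ndim)


def load_state(path):
    out = {}
    with h5py.File(path, "r") as fh:
        for name in fh:
            out[name] = fh[name][()]
        out.update(dict(fh.attrs))
    return out


def _axes_hint(name, ndim):
    if name in ("tp", "t1"):
        return "occupied_pair x virtual"
    if name == "lam_p":
        return "virtual x occupied_pair"
    if name in ("t2", "l2"):
        return "occ x occ x virt x virt"
    if name.startswith(("gamma", "rdm")):
        return "mo x mo"
    if name in ("U", "C"):
        return "row-basis x column-orbital"
    return f"{ndim}-dim array"
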