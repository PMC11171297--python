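"""Dipole moments, finite-field validation, dipole-moment surfaces.

Sign conventions: internal dipoles are atomic units; reporting is Debye.
mu = mu_nuc + mu_el with mu_el = -Tr(D d) (electrons negative).  For a
diatomic A--B with A at the origin and B on +z, positive mu_z means
A(-)B(+) polarity and negative mu_z means A(+)B(-).

The electronic Hamiltonian is perturbed as h -> h - eps*d_alpha, so
dE/d eps = mu_el,alpha; the finite-field routines return the full dipole
by adding the (field-independent) nuclear part.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import oopccd, pccd
from .integrals import ao as aomod
from .lcc import (LCCWorkspace, combine_rdm, lcc_correlation_1rdm, solve_lcc,
                  solve_lcc_lambda)
from .mo import fold_frozen_core, transform_to_mo
from .integrals.basis import atom_ao_map
from .molecule import Molecule
from .scf import pipek_mezey_localize, solve_rhf, rhf_dipole
from .units import au_to_debye

METHODS = ("rhf", "pccd", "oo-pccd", "pccd-lccd", "pccd-lccsd",
           "oo-pccd-lccd", "oo-pccd-lccsd")


@dataclass
class DipoleResult:
    mu: np.ndarray                # Debye, 3-vector
    nuclear_part: np.ndarray      # Debye
    electronic_part: np.ndarray   # Debye
    method: str
    origin: np.ndarray            # bohr

    def __post_init__(self):
        assert np.allclose(self.mu, self.nuclear_part + self.electronic_part,
                           atol=1e-10)


@dataclass
class ErrorStats:
    mue: float
    rmse: float
    n: int


def error_stats(values, references) -> ErrorStats:
    """Mean unsigned error and root-mean-square error (same units as in)."""
    v = np.asarray(values, float)
    r = np.asarray(references, float)
    if v.size == 0 or v.shape != r.shape:
        raise ValueError("need equal-length, nonempty value/reference lists")
    d = v - r
    return ErrorStats(mue=float(np.abs(d).mean()),
                      rmse=float(np.sqrt((d * d).mean())), n=int(v.size))


# ---------------------------------------------------------------------------
# dipole assembly
# ---------------------------------------------------------------------------
def electronic_dipole_mo(gamma_active, dipole_mo_active, core_dipole_au):
    """Electronic dipole (a.u.): -[Tr(gamma d_MO) + 2 sum_core d_cc]."""
    mu = -np.einsum("pq,xpq->x", gamma_active, dipole_mo_active)
    return mu - core_dipole_au


def electronic_dipole_ao(gamma_active, C_active, C_core, ao_dipole):
    """Same quantity via AO back-transformation of the density."""
    D = C_active @ gamma_active @ C_active.T
    if C_core is not None and C_core.shape[1]:
        D = D + 2.0 * C_core @ C_core.T
    return -np.einsum("pq,xpq->x", D, ao_dipole)


def total_dipole(molecule: Molecule, electronic_au, origin, method
                 ) -> DipoleResult:
    nuc = molecule.nuclear_dipole(origin)
    return DipoleResult(mu=au_to_debye(nuc + electronic_au),
                        nuclear_part=au_to_debye(nuc),
                        electronic_part=au_to_debye(np.asarray(electronic_au)),
                        method=method, origin=np.asarray(origin, float))


# ---------------------------------------------------------------------------
# the method pipeline
# ---------------------------------------------------------------------------
@dataclass
class WarmStart:
    C_scf: np.ndarray | None = None
    U: np.ndarray | None = None
    tp: np.ndarray | None = None
    C_mo: np.ndarray | None = None   # full optimized MO basis to propagate
    shells: list | None = None       # shell set the C_mo coefficients refer to


@dataclass
class MethodState:
    """Everything a single-point calculation produced."""

    molecule: Molecule
    method: str
    aoints: aomod.AOIntegralSet
    scf: object
    moints_active: object          # in the method's orbital basis
    n_pairs: int
    frozen: list
    U: np.ndarray                  # active-space rotation (identity if none)
    pccd_result: object | None
    lcc_result: object | None
    gamma_active: np.ndarray | None
    energy: float
    dipole: DipoleResult
    C_mo_full: np.ndarray | None = None   # AO x MO basis incl. optimization


def _propagate_orbitals(C_old, shells_old, aoints_new):
    """Re-express a previous-geometry MO basis at a new geometry.

    The coefficients are reused as-is -- atom-centered AOs make this the
    atom-following (chemically continuous) propagation -- and then
    re-orthonormalized in the new metric by a CHOLESKY factorization of
    the Gram matrix: column k mixes only with columns < k, so the
    core/occupied/virtual identity of each orbital survives.  (A symmetric
    Loewdin orthonormalization scrambles that identity here, and a
    fixed-in-space function projection loses the cores of moving atoms.)"""
    M = C_old.T @ aoints_new.overlap @ C_old
    L = np.linalg.cholesky(M)
    return np.linalg.solve(L, C_old.T).T


def _resolve_frozen(molecule, freeze):
    if freeze == "auto":
        return molecule.n_frozen_core_orbitals()
    if freeze in (None, "none"):
        return 0
    return int(freeze)


def run_method(molecule: Molecule, basis: str, method: str, freeze="auto",
               store="cholesky", origin=None, warm: WarmStart | None = None,
               oopccd_opts=None, aoints=None, localize="occ",
               cholesky_threshold=1e-5) -> MethodState:
    """Run the full pipeline for one geometry and method; returns the state
    including the response 1-RDM and the dipole.

    For the orbital-optimized methods the active occupied block is
    Pipek-Mezey localized before the optimization (``localize='occ'``,
    default) unless warm-start orbitals are supplied; localization speeds
    up the orbital optimization substantially and does not change the
    optimum."""
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    nfc = _resolve_frozen(molecule, freeze)
    if aoints is None:
        aoints = aomod.build_from_backend(
            molecule, basis, origin=origin, store=store,
            cholesky_threshold=cholesky_threshold)
    nelec = molecule.n_electrons
    propagate = (warm is not None and warm.C_mo is not None
                 and method.startswith("oo-"))
    if propagate:
        # propagate the previous point's optimized orbitals instead of
        # re-deriving an SCF/localized basis (scan continuity)
        from .scf import SCFResult
        from .mo import MOCoefficients
        C0 = _propagate_orbitals(warm.C_mo, warm.shells, aoints)
        nocc = nelec // 2
        moc = MOCoefficients(C=C0, frozen_core=list(range(nfc)),
                             occupied_pairs=list(range(nfc, nocc)),
                             virtuals=list(range(nocc, C0.shape[1])))
        scf = SCFResult(mocoeffs=moc, orbital_energies=np.zeros(C0.shape[1]),
                        E_total=float("nan"), converged=True, iterations=0)
    else:
        scf = solve_rhf(aoints, nelec, guess_C=warm.C_scf if warm else None,
                        n_frozen_core=nfc)
        if warm is not None and warm.C_scf is not None:
            from .scf import align_orbitals
            C = scf.mocoeffs.C
            nocc = nelec // 2
            C[:, :nocc] = align_orbitals(C[:, :nocc], warm.C_scf[:, :nocc],
                                         aoints.overlap)
            C[:, nocc:] = align_orbitals(C[:, nocc:], warm.C_scf[:, nocc:],
                                         aoints.overlap)
    n_pairs = nelec // 2 - nfc
    if method == "rhf":
        mu_el = rhf_dipole(aoints, scf, molecule) - molecule.nuclear_dipole(
            aoints.origin)
        dip = total_dipole(molecule, mu_el, aoints.origin, method)
        return MethodState(molecule, method, aoints, scf, None, n_pairs,
                           list(range(nfc)), np.eye(aoints.n_basis - nfc),
                           None, None, None, scf.E_total, dip)

    mi = transform_to_mo(aoints, scf.mocoeffs.C)
    mia = fold_frozen_core(mi, list(range(nfc)))
    core_idx = np.arange(nfc)
    core_dip = 2.0 * np.einsum("xcc->x", mi.dipole[:, core_idx][:, :, core_idx]) \
        if nfc else np.zeros(3)

    U = np.eye(mia.n)
    if method.startswith("oo-"):
        if (localize == "occ" and not propagate
                and (warm is None or warm.U is None) and n_pairs > 1):
            C_loc = pipek_mezey_localize(
                scf.mocoeffs.C, aoints.overlap, atom_ao_map(aoints.shells),
                np.arange(nfc, nfc + n_pairs))
            # record the orbitals that actually define the MO basis, so
            # downstream consumers (finite-field, warm starts) agree with U
            scf.mocoeffs.C = C_loc
            mi = transform_to_mo(aoints, C_loc)
            mia = fold_frozen_core(mi, list(range(nfc)))
            if nfc:
                core_idx = np.arange(nfc)
                core_dip = 2.0 * np.einsum(
                    "xcc->x", mi.dipole[:, core_idx][:, :, core_idx])
        if warm is not None and warm.U is not None and not propagate:
            mia = mia.rotate(warm.U)
            U = warm.U.copy()
        oo = oopccd.solve_oopccd(mia, n_pairs,
                                 guess_t=warm.tp if warm else None,
                                 **(oopccd_opts or {}))
        mia = oo.moints
        U = U @ oo.U
        pres = oo.pccd
        gamma_ref = oopccd.relaxed_reference_rdm(oo)
    else:
        pres = pccd.solve_pccd(mia, n_pairs, guess=warm.tp if warm else None)
        pres.lam = pccd.solve_pccd_lambda(pres.t.t, mia, n_pairs)
        gamma_ref = pccd.pccd_response_1rdm(pres.t.t, pres.lam)

    energy = pres.energy
    lres = None
    gamma = gamma_ref
    if "lcc" in method:
        variant = method.split("-")[-1]
        ws = LCCWorkspace(mia, n_pairs, pres.t.t)
        lres = solve_lcc(pres.t.t, mia, n_pairs, variant, ws=ws)
        lam = solve_lcc_lambda(lres, pres.t.t, mia, n_pairs, ws=ws)
        lres.lam = lam
        gamma_lcc = lcc_correlation_1rdm(lres, lam, pres.t.t, mia, n_pairs,
                                         ws=ws)
        gamma = combine_rdm(gamma_ref, gamma_lcc)
        energy = energy + lres.E_lcc

    mu_el = electronic_dipole_mo(gamma, mia.dipole, core_dip)
    dip = total_dipole(molecule, mu_el, aoints.origin, method)
    C_full = scf.mocoeffs.C.copy()
    C_full[:, nfc:] = C_full[:, nfc:] @ U
    return MethodState(molecule, method, aoints, scf, mia, n_pairs,
                       list(range(nfc)), U, pres, lres, gamma, energy, dip,
                       C_mo_full=C_full)


def add_lcc_correction(state: MethodState, variant: str) -> MethodState:
    """LCCD/LCCSD correction (with Lambda equations and the combined
    density) on an existing pCCD/oo-pCCD state, reusing its orbitals and
    pair amplitudes."""
    if state.lcc_result is not None or state.pccd_result is None:
        raise ValueError("need a bare pCCD/oo-pCCD state")
    mia = state.moints_active
    n_pairs = state.n_pairs
    tp = state.pccd_result.t.t
    ws = LCCWorkspace(mia, n_pairs, tp)
    lres = solve_lcc(tp, mia, n_pairs, variant, ws=ws)
    lam = solve_lcc_lambda(lres, tp, mia, n_pairs, ws=ws)
    lres.lam = lam
    gamma_ref = pccd.pccd_response_1rdm(tp, state.pccd_result.lam)
    gamma = combine_rdm(gamma_ref,
                        lcc_correlation_1rdm(lres, lam, tp, mia, n_pairs,
                                             ws=ws))
    nfc = len(state.frozen)
    if nfc:
        mi_dip = state.aoints.dipole_ints
        # frozen-core dipole in the SCF MO basis
        C_core = state.scf.mocoeffs.C[:, :nfc]
        core_dip = 2.0 * np.einsum("xpq,pc,qc->x", mi_dip, C_core, C_core)
    else:
        core_dip = np.zeros(3)
    mu_el = electronic_dipole_mo(gamma, mia.dipole, core_dip)
    dip = total_dipole(state.molecule, mu_el, state.aoints.origin,
                       state.method + "-" + variant)
    return MethodState(state.molecule, state.method + "-" + variant,
                       state.aoints, state.scf, mia, n_pairs, state.frozen,
                       state.U, state.pccd_result, lres, gamma,
                       state.energy + lres.E_lcc, dip)


# ---------------------------------------------------------------------------
# finite-field oracle
# ---------------------------------------------------------------------------
def finite_field_dipole(molecule: Molecule, basis: str, method: str,
                        freeze="auto", eps=1e-4, axes=(2,), store="dense",
                        origin=None) -> np.ndarray:
    """Central-difference dipole (Debye per requested axis, full 3-vector
    with zeros elsewhere) under the method's freezing protocol:

    * rhf: SCF re-solved per field point.
    * pccd / pccd-lcc*: orbitals fixed at their zero-field shapes; pair
      amplitudes re-solved for the pCCD part; for the LCC part the pair
      amplitudes are additionally frozen and only T' is re-solved.
    * oo-pccd / oo-pccd-lcc*: orbitals re-optimized per field for the pCCD
      part (warm-started); same frozen-(orbitals, tp) rule for the LCC part.
      LCC orbital response is never included, matching the response density.
    """
    method = method.lower()
    base = run_method(molecule, basis, method if method != "rhf" else "rhf",
                      freeze=freeze, store=store, origin=origin)
    nfc = len(base.frozen)
    aoints = base.aoints

    def energy_at(eps_vec):
        pert = aomod.AOIntegralSet(**{**aoints.__dict__})
        pert.v_embedding = (aoints.v_embedding if aoints.v_embedding
                            is not None else 0.0) \
            - np.einsum("x,xpq->pq", eps_vec, aoints.dipole_ints)
        if method == "rhf":
            return solve_rhf(pert, molecule.n_electrons,
                             guess_C=base.scf.mocoeffs.C).E_total
        # fixed SCF orbitals; field folded through the frozen core
        mi = transform_to_mo(pert, base.scf.mocoeffs.C)
        mia = fold_frozen_core(mi, list(range(nfc)))
        n_pairs = base.n_pairs
        if method.startswith("oo-"):
            oo = oopccd.solve_oopccd(mia.rotate(base.U), n_pairs,
                                     guess_t=base.pccd_result.t.t)
            E_ref = oo.energy
            mia_ref = oo.moints
        else:
            pres = pccd.solve_pccd(mia, n_pairs, guess=base.pccd_result.t.t)
            E_ref = pres.energy
            mia_ref = mia
        if "lcc" not in method:
            return E_ref
        # unrelaxed LCC: orbitals and tp frozen at zero field
        variant = method.split("-")[-1]
        mia_frozen = mia.rotate(base.U)
        lres = solve_lcc(base.pccd_result.t.t, mia_frozen, n_pairs, variant)
        return E_ref + lres.E_lcc

    mu = molecule.nuclear_dipole(aoints.origin if origin is None else origin)
    out = au_to_debye(mu.astype(float))
    out = np.where(np.isin(np.arange(3), list(axes)), out, 0.0)
    for ax in axes:
        ev = np.zeros(3)
        ev[ax] = eps
        dmu = (energy_at(ev) - energy_at(-ev)) / (2.0 * eps)
        out[ax] += au_to_debye(dmu)
    return out


# ---------------------------------------------------------------------------
# dipole-moment surfaces
# ---------------------------------------------------------------------------
@dataclass
class DMSCurve:
    r: np.ndarray                 # Angstrom, strictly increasing
    mu_z: np.ndarray              # Debye
    converged: np.ndarray         # bool per point
    method: str
    energies: np.ndarray | None = None

    def __post_init__(self):
        if not np.all(np.diff(self.r) > 0):
            raise ValueError("scan grid must be strictly increasing")

    def to_csv(self, path):
        pd.DataFrame({"r_angstrom": self.r,
                      "mu_z_debye": np.round(self.mu_z, 6),
                      "converged": self.converged.astype(bool)}
                     ).to_csv(path, index=False)


def scan_dms(element_a: str, element_b: str, r_grid, method: str,
             basis: str, freeze="auto", store="cholesky", start_index=None,
             oopccd_opts=None, verbose=False) -> DMSCurve:
    """Dipole-moment surface of the diatomic A--B (A at origin, B on +z).

    Points are visited outward from ``start_index`` (default: middle of the
    grid) in both directions so warm-started orbitals and amplitudes
    propagate; per-point failures are flagged, never interpolated over.
    """
    r_grid = np.asarray(r_grid, float)
    npts = r_grid.size
    i0 = npts // 2 if start_index is None else int(start_index)
    order = [i0]
    for k in range(1, npts):
        for j in (i0 - k, i0 + k):
            if 0 <= j < npts:
                order.append(j)
    mu = np.full(npts, np.nan)
    en = np.full(npts, np.nan)
    ok = np.zeros(npts, bool)
    warm_lo = warm_hi = None
    for j in order:
        warm = warm_lo if j <= i0 else warm_hi
        mol = Molecule.diatomic(element_a, element_b, r_grid[j])
        try:
            st = run_method(mol, basis, method, freeze=freeze, store=store,
                            warm=warm, oopccd_opts=oopccd_opts)
            mu[j] = st.dipole.mu[2]
            en[j] = st.energy
            ok[j] = True
            w = WarmStart(C_scf=st.scf.mocoeffs.C,
                          tp=st.pccd_result.t.t if st.pccd_result else None,
                          C_mo=st.C_mo_full, shells=st.aoints.shells)
            if j <= i0:
                warm_lo = w
            if j >= i0:
                warm_hi = w
        except RuntimeError as exc:
            if verbose:
                print(f"  scan point r={r_grid[j]:.3f} failed: {exc}")
        if verbose and ok[j]:
            print(f"  r={r_grid[j]:.3f}  mu_z={mu[j]:+.4f} D")
    return DMSCurve(r=r_grid, mu_z=mu, converged=ok, method=method,
                    energies=en)


def turning_point(curve: DMSCurve):
    """Abscissa (Angstrom) of the interior maximum of mu_z(r), refined by a
    three-point quadratic fit; None if the maximum sits on the grid edge."""
    r = curve.r[curve.converged]
    y = curve.mu_z[curve.converged]
    if r.size < 3 or y.max() - y.min() < 1e-8:
        return None
    k = int(np.argmax(y))
    if k == 0 or k == r.size - 1:
        return None
    x0, x1, x2 = r[k - 1:k + 2]
    y0, y1, y2 = y[k - 1:k + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 * x2 * (y0 - y1) + x1 * x1 * (y2 - y0)
         + x0 * x0 * (y1 - y2)) / denom
    if a >= 0:
        return None
    return float(-b / (2 * a))


def read_reference_csv(path):
    """Reference dipole tables: columns molecule, method, value (Debye)."""
    return pd.read_csv(path)
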