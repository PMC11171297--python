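"""Restricted Hartree-Fock and Pipek-Mezey orbital localization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .mo import MOCoefficients


@dataclass
class SCFResult:
    mocoeffs: MOCoefficients
    orbital_energies: np.ndarray
    E_total: float
    converged: bool
    iterations: int


def _fock_ao(aoints, Dm):
    """Closed-shell Fock matrix from AO density D (sum over spins)."""
    h = aoints.core_hamiltonian
    if aoints.eri is not None:
        J = np.einsum("pqrs,rs->pq", aoints.eri, Dm, optimize=True)
        K = np.einsum("prqs,rs->pq", aoints.eri, Dm, optimize=True)
    else:
        L = aoints.chol.vectors
        c = np.einsum("Prs,rs->P", L, Dm, optimize=True)
        J = np.einsum("P,Ppq->pq", c, L, optimize=True)
        X = np.einsum("Ppr,rs->Pps", L, Dm, optimize=True)
        K = np.einsum("Pps,Pqs->pq", X, L, optimize=True)
    return h + J - 0.5 * K


def solve_rhf(aoints, nelec, tol_grad=1e-8, tol_energy=1e-10, maxiter=200,
              diis_size=8, level_shift=0.0, guess_C=None,
              n_frozen_core=0) -> SCFResult:
    """DIIS-accelerated RHF from the diagonalized-core-Hamiltonian guess.

    Deterministic; fails loudly on non-convergence with the last energy.
    ``level_shift`` (Ha) raises virtual orbitals during the early
    iterations, for stretched geometries where plain SCF oscillates.
    """
    if nelec % 2:
        raise ValueError("RHF requires an even electron count")
    n = aoints.n_basis
    nocc = nelec // 2
    if nocc > n:
        raise ValueError("more electron pairs than basis functions")
    S = aoints.overlap
    h = aoints.core_hamiltonian
    # symmetric orthogonalization
    w, U = np.linalg.eigh(S)
    if w.min() < 1e-10:
        keep = w > 1e-10
        X = U[:, keep] / np.sqrt(w[keep])
    else:
        X = U / np.sqrt(w)

    def diag_fock(F):
        Fp = X.T @ F @ X
        e, Cp = np.linalg.eigh(Fp)
        return e, X @ Cp

    if guess_C is None:
        _, C = diag_fock(h)
    else:
        C = guess_C
    from .pccd import DIIS
    diis = DIIS(diis_size)
    e_old = np.inf
    E = np.inf
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        Dm = 2.0 * C[:, :nocc] @ C[:, :nocc].T
        F = _fock_ao(aoints, Dm)
        E = 0.5 * np.einsum("pq,pq->", Dm, h + F) + aoints.nuclear_repulsion
        grad = F @ Dm @ S - S @ Dm @ F
        gnorm = np.abs(grad).max()
        if gnorm < tol_grad and abs(E - e_old) < tol_energy:
            converged = True
            break
        e_old = E
        Fd = F
        if level_shift and gnorm > 1e-3:
            P_virt = S - 0.5 * S @ Dm @ S  # projector-ish onto virtuals
            Fd = F + level_shift * (S @ (np.eye(n) - 0.5 * Dm @ S))
            Fd = 0.5 * (Fd + Fd.T)
        Fd = diis.step(Fd, grad)
        eps, C = diag_fock(Fd)
    if not converged:
        raise RuntimeError(f"SCF failed to converge in {maxiter} iterations; "
                           f"last E = {E:.10f}")
    eps, C = diag_fock(F)
    nmo = C.shape[1]
    moc = MOCoefficients(C=C, frozen_core=list(range(n_frozen_core)),
                         occupied_pairs=list(range(n_frozen_core, nocc)),
                         virtuals=list(range(nocc, nmo)))
    moc.check_orthonormal(S)
    return SCFResult(mocoeffs=moc, orbital_energies=eps, E_total=float(E),
                     converged=True, iterations=it)


def rhf_dipole(aoints, scf: SCFResult, molecule):
    """SCF dipole (a.u.) about the integral origin: nuclear minus electronic."""
    nocc = len(scf.mocoeffs.frozen_core) + len(scf.mocoeffs.occupied_pairs)
    C = scf.mocoeffs.C
    Dm = 2.0 * C[:, :nocc] @ C[:, :nocc].T
    mu_el = -np.einsum("xpq,pq->x", aoints.dipole_ints, Dm)
    return molecule.nuclear_dipole(aoints.origin) + mu_el


def align_orbitals(C_new, C_ref, S):
    """Permute/sign-fix the columns of C_new to best match C_ref (max
    overlap).  Keeps warm starts meaningful when eigensolver ordering or
    signs drift between neighbouring scan geometries."""
    O = C_ref.T @ S @ C_new
    n = C_new.shape[1]
    out = np.empty_like(C_new)
    used = np.zeros(n, bool)
    for i in range(n):
        j = int(np.argmax(np.where(used, -1.0, np.abs(O[i]))))
        used[j] = True
        out[:, i] = C_new[:, j] * np.sign(O[i, j])
    return out


# ---------------------------------------------------------------------------
# Pipek-Mezey localization
# ---------------------------------------------------------------------------
def pm_functional(C_block, S, atom_map, natom):
    """Sum of squared Mulliken atomic charges over the orbital block."""
    val = 0.0
    SC = S @ C_block
    for A in range(natom):
        mask = atom_map == A
        QA = 0.5 * (C_block[mask].T @ SC[mask]
                    + SC[mask].T @ C_block[mask])
        val += float((np.diag(QA) ** 2).sum())
    return val


def pipek_mezey_localize(C, S, atom_map, block, max_sweeps=200,
                         tol_angle=1e-8):
    """Jacobi-sweep Pipek-Mezey localization of one orbital block.

    ``block`` is an index array selecting the occupied or the virtual
    subspace; mixing across the block boundary never occurs.  Returns the
    full C with the block rotated (still S-orthonormal); the PM functional
    ascends monotonically over sweeps.
    """
    C = C.copy()
    idx = np.asarray(block, dtype=int)
    nb = idx.size
    if nb < 2:
        return C
    natom = int(atom_map.max()) + 1
    for _ in range(max_sweeps):
        max_angle = 0.0
        SC = S @ C
        for si in range(nb):
            for sj in range(si + 1, nb):
                s, t = idx[si], idx[sj]
                Ast = Bst = 0.0
                for A in range(natom):
                    m = atom_map == A
                    Qss = C[m, s] @ SC[m, s]
                    Qtt = C[m, t] @ SC[m, t]
                    Qst = 0.5 * (C[m, s] @ SC[m, t] + C[m, t] @ SC[m, s])
                    Ast += Qst * Qst - 0.25 * (Qss - Qtt) ** 2
                    Bst += Qst * (Qss - Qtt)
                if abs(Ast) < 1e-16 and abs(Bst) < 1e-16:
                    continue
                # maximize: rotation angle gamma with 4*gamma from atan2
                gamma = 0.25 * np.arctan2(Bst, -Ast)
                if abs(gamma) < tol_angle:
                    continue
                max_angle = max(max_angle, abs(gamma))
                cg, sg = np.cos(gamma), np.sin(gamma)
                cs, ct = C[:, s].copy(), C[:, t].copy()
                C[:, s] = cg * cs + sg * ct
                C[:, t] = -sg * cs + cg * ct
                SC[:, s] = S @ C[:, s]
                SC[:, t] = S @ C[:, t]
        if max_angle < tol_angle:
            break
    return C
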