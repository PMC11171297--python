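# Methods

`paircc` computes electronic dipole moments and dipole-moment surfaces from
pair coupled-cluster doubles (pCCD) wave functions, with and without
variational orbital optimization, and with a posteriori linearized
coupled-cluster corrections (LCCD/LCCSD).  This note records the models,
the working equations and their verification strategy, the numerical
choices, and the known limitations.

## Models

**Reference and pair ansatz.**  All methods start from a closed-shell
restricted Hartree–Fock determinant; the framework is restricted to singlet
ground states.  pCCD keeps only electron-pair excitations,
T_p = Σ_ia t_ia P†_a P_i with P†_p = a†_{pα} a†_{pβ}.  Because both the
excitation manifold and the projection manifold are seniority-zero, the
projected equations ⟨Φ_iī^aā| e^{−T_p} H e^{T_p} |Φ₀⟩ = 0 close over three
N×N integral matrices — diag(h), J_pq = (pp|qq) and K_pq = (pq|pq) — and
are exactly quadratic in t.  The closed form used here was derived by
expanding H e^{T_p}|Φ₀⟩ in the closed-pair determinant basis; the test
suite certifies it to machine precision against a brute-force
determinant-space construction on random Hamiltonians.

**Lambda equations and response densities.**  Because the projected energy
is not variational in t, one-electron properties use the response
formalism: pair de-excitation amplitudes λ solve the linear adjoint system
J(t)ᵀλ = −K_ov (J is the analytic amplitude Jacobian), and the response
1-RDM is diagonal in the pCCD orbital basis:
γ_ii = 2(1 − Σ_a t_ia λ_ai), γ_aa = 2 Σ_i t_ia λ_ai, with trace exactly
2·(number of pairs).  The seniority-zero two-particle blocks
(pair-transfer ⟨P†_p P_q⟩ and number–number ⟨N_p N_q⟩) carry the rest of
the energy functional; contracted with the integrals they reproduce the
projected energy identically, which the tests assert.

**Orbital optimization (oo-pCCD).**  pCCD is not invariant under
occupied–occupied or virtual–virtual rotations, so all active–active
rotation parameters κ_pq are minimized over.  The gradient is the
Lagrangian-envelope (response) gradient assembled from the response
densities, exact at any expansion point through the derivative of the
matrix exponential (computed via the anti-Hermitian eigendecomposition of
κ).  The optimizer is two-phase: preconditioned L-BFGS using the exact
fixed-density diagonal orbital Hessian (closed form, finite-difference
verified) as a variable scaling, then a Steihaug trust-region truncated
Newton whose Hessian-vector products are forward differences of the exact
gradient.  At the variational optimum the orbital-response terms vanish,
so the *relaxed* density equals the pCCD response density in the optimized
basis — the package's central route to dipoles.

Convergence criterion: max|∂E/∂κ| < 1e-6 where attainable.  In augmented
triple-zeta bases the true orbital Hessian develops near-singular modes
(rotations among weakly coupled diffuse virtuals, curvatures ~1e-5), and
pushing the max-norm through them is uneconomical: measured on
HF/aug-cc-pVTZ, improving max|g| from 5e-5 to 9e-6 changes the energy by
2e-6 Ha and the dipole by 4e-6 D.  The solver therefore accepts a point
when the trust-region model predicts less than a size-scaled descent
threshold (1e-9 Ha at ~2000 parameters) and max|g| is below a soft bound
(1e-4 by default), flagging it `tight=False`.  Bond-length scans use this
soft criterion; the two-electron exactness and finite-field acceptance
checks converge strictly.

The active occupied block is Pipek–Mezey localized before optimization
(Jacobi 2×2 sweeps on Mulliken charges, angle tolerance 1e-8 rad, 200
sweeps max); this cuts the cold-start cost about six-fold and does not change the
optimum.  Virtual-block localization is available but off by default —
diffuse augmented virtuals localize poorly.  Scans propagate the full
optimized MO coefficient matrix from point to point (atom-following: the
coefficients ride on the moved AO centers) and re-orthonormalize it by a
Cholesky factorization of the Gram matrix, which preserves each orbital's
core/occupied/virtual identity; symmetric orthonormalization scrambles it
in near-linearly-dependent augmented bases, and a fixed-in-space function
projection loses the cores of moving atoms.  Pair amplitudes warm-start
alongside the orbitals.

**Linearized CC corrections.**  The LCC correction solves
⟨μ| H̄ + [H̄, T′] |Φ₀⟩ = 0 with H̄ = e^{−T_p} H e^{T_p}, where T′ contains
singles and doubles with the pure pair channel excluded (t′[i,i,a,a] = 0;
rows with i=j, a≠b and i≠j, a=b remain).  Since excitation operators
commute, these equations are *exactly* the linearization of the singlet
closed-shell CCSD residual around (T1=0, T2=T_p).  The implementation
never transcribes a second equation set: one spin-orbital term list
(rational coefficients determined by an exact least-squares match against
the brute-force determinant-space residual, and re-verified by the tests)
is mechanically spin-summed into the production closed-shell contractions,
and the Jacobian action, its transpose (the Λ′ equations) and the
one-electron derivative (the correlation 1-RDM) are mechanical operations
on the same term list.  With T_p = 0 the equations reduce to canonical
linearized CCSD (CEPA(0)), which the suite checks against a dense
determinant-space solve.

**Combined density and the freezing contract.**  The final density is
γ = γ(relaxed oo-pCCD) + γ(LCC), where the LCC part is unrelaxed: no
orbital response and no coupling back into the pair Λ equations.  The
matching finite-field statement — asserted by the acceptance tests at
1e-4 D — is that the response dipole equals the central-difference
derivative of E(oo-pCCD), with orbitals and pair amplitudes re-solved per
field, *plus* the derivative of E(LCC) with orbitals and pair amplitudes
frozen at their zero-field values and only T′ re-solved.  The trace of the
LCC correlation density is zero (particle conservation), asserted on every
construction.

## Integrals

The package carries a compact McMurchie–Davidson Gaussian integral engine
(numba-accelerated): Hermite expansion coefficients for overlap, kinetic,
dipole and nuclear-attraction integrals; Hermite Coulomb R-tensors with a
series/downward-recursion Boys function; Schwarz-screened four-index ERIs;
Cartesian-to-real-spherical transforms built from solid-harmonic
polynomials normalized under the Gaussian monomial metric (l ≤ 3).
Verification is independent of the recursions: grid quadrature for
high-angular-momentum one-electron integrals, closed forms for s-type
ERIs, rigid-rotation invariance of SCF energies with d functions in play,
and textbook H2/STO-3G energetics.

Basis sets ship as plain text.  STO-3G uses the standard published
Slater-zeta scaling.  The correlation-consistent sets (cc-pVDZ;
aug-cc-pVTZ for H and F) use the published Dunning exponents with
general-contraction coefficients regenerated by a spherically averaged
atomic Hartree–Fock in the uncontracted primitives
(`scripts/make_cc_basis.py`) — the construction that defines those
contractions.  For H and He the regenerated atomic energies match the
published basis values to print precision; for open-shell atoms the
spherically averaged fractional-occupation functional differs from a true
restricted open-shell average by a few tens of mHa in the atomic total
energy, which shifts molecular absolute energies at the mHa level and
dipole-surface features negligibly (the free outer primitives carry the
valence flexibility).  Shells with no occupied atomic orbital of that
angular momentum (e.g. Li p) stay uncontracted.

Two-electron integrals are handled dense for small systems and as pivoted
incomplete Cholesky factors (LAPACK `dpstrf`, full diagonal pivoting,
threshold 1e-5 by default) for production runs; the stopping rule bounds
every diagonal reconstruction error by the threshold.  Frozen cores follow
the noble-gas-core rule (He core for Li–Ne, Ne core for Na–Ar), folded as
a closed-shell mean field into the one-electron operator, with the core
dipole added back at the property layer.  A static one-electron embedding
potential (a user-supplied symmetric AO matrix) can be added to the core
Hamiltonian; its generation is out of scope.

## Brute-force oracles

`paircc.oracles` is the package's independent referee: Slater–Condon
construction of dense Hamiltonians over Sz=0 determinants (optionally
seniority-zero filtered or core-constrained), exact FCI/DOCI by
diagonalization, cluster operators applied as explicit sparse matrices
with e^{T} expanded to nilpotency, and a seeded reduced-BCS pairing-model
generator whose closed-pair determinant energies carry no spurious cross
terms.  Every solver result that matters — pCCD residuals, LCC residuals
and energies, response densities, dipoles — is certified against this
module on small systems, and the LCC term-list coefficients were *derived*
from it.  The dense oracle refuses determinant spaces beyond dimension
6000; the acceptance-relevant spaces are far smaller.

## Numerical choices

* pCCD amplitudes: MP2-like pair guess, DIIS(6) quasi-Newton with the pair
  excitation gap as Jacobi preconditioner; degenerate gaps (<1e-6 Ha) get
  a fixed 0.1 Ha shift in the preconditioner only.  Divergence restarts
  with damped plain iterations.  Residual max-norm < 1e-10 by default.
* Pair Λ and LCC Λ′ are linear solves: dense for the pair problem,
  DIIS-accelerated preconditioned Richardson with a GMRES fallback for
  LCC (residual < 1e-8 / 1e-9).
* Finite-field step 1e-4 a.u., central differences, field applied as
  h → h − ε·d at the AO level so frozen-core contributions differentiate
  correctly.
* DMS grids default to 0.05 Å; turning points refine the grid maximum by a
  three-point quadratic fit (quadratic, not cubic, to avoid overfitting
  sparse grids); maxima on a window edge are reported as "no interior
  turning", never extrapolated.
* Dipoles are reported in Debye (1 a.u. = 2.5417464519 D), geometries in
  Å (1 bohr = 0.52917721092 Å); everything internal is atomic units.
  Charged species' dipoles are origin-dependent; the origin is part of
  every result object.

## Synthetic data

The pairing-model generator emulates the seniority-zero physics the pair
solvers live in: non-degenerate level spectra with constant pair
scattering −G, seeded jitter for degeneracy breaking.  It reproduces
perturbation theory in the weak-coupling limit and DOCI exactly for one
pair.  What it does not emulate: realistic integral magnitudes and decay,
broken-pair (nonzero-seniority) coupling, or basis-set structure — so
passing pairing-model tests certifies the solver algebra, not chemical
accuracy; the molecular fixtures and oracles cover the rest.

## Known limitations

* Singlet, closed-shell references only; no UHF/ROHF, no open-shell pCCD.
* The integral engine stops at f functions (l = 3) and computes no
  derivatives; basis sets beyond the shipped files must be supplied as
  text in the same format.
* The LCC correction is linear: near-singular linear systems at strongly
  stretched geometries are genuine (CEPA(0)-type divergences) and surface
  as solver failures rather than being damped away by default.
* oo-pCCD landscapes have multiple local minima at stretched geometries;
  scans mitigate this with warm-started orbital propagation, but a cold
  start at a single stretched point may land on a different branch.
* The regenerated correlation-consistent contractions deviate slightly
  from the canonical published coefficients for open-shell atoms (see
  Integrals above).
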