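# paircc

Electronic dipole moments and dipole-moment surfaces from pair
coupled-cluster doubles (pCCD) wave functions: canonical and
orbital-optimized pCCD, a posteriori linearized coupled-cluster
corrections (LCCD/LCCSD), Λ-equation response one-particle densities, and
bond-stretching scans — over a self-contained Gaussian-integral engine,
with brute-force determinant-space oracles certifying every solver.

## The problem

Strongly correlated closed-shell molecules (stretched bonds, dissociation)
break single-reference coupled cluster, yet their one-electron properties
— above all dipole moments μ(r) along a dissociation coordinate — are what
rovibrational spectroscopy needs.  pCCD keeps only electron-pair
excitations,

    |Ψ⟩ = exp(T_p)|Φ₀⟩,   T_p = Σ_ia t_i^a a†_{aα} a†_{aβ} a_{iβ} a_{iα},

a seniority-zero ansatz that survives bond breaking at mean-field cost.
Variationally optimizing its orbitals (oo-pCCD) removes the dependence on
the Hartree–Fock canonical basis; linearized CC corrections (LCCD/LCCSD —
the cluster correction T′ kept to first order, pair channel excluded)
restore dynamic correlation.  Dipoles come from the response formalism:

    μ_α = Σ_i Z_i R_{i,α} − Tr(D d^α),

where D is back-transformed from the MO-basis response 1-RDM
γ = γ(relaxed oo-pCCD) + γ(unrelaxed LCC), assembled from the converged
amplitudes and their Λ (de-excitation) companions.  A finite-field oracle
(central differences of the energy under h → h − ε d^α, with each method's
freezing protocol) validates every analytic density the package produces.

## Worked example

```python
from paircc.molecule import Molecule
from paircc.properties import run_method

mol = Molecule.diatomic("H", "F", 0.917)   # H at origin, F on +z
st = run_method(mol, "cc-pvdz", "oo-pccd-lccd")
print(f"E(oo-pCCD-LCCD) = {st.energy:.6f} Ha")
print(f"mu_z = {st.dipole.mu[2]:.3f} D")
```

prints (computed by this code)

```
E(oo-pCCD-LCCD) = -100.209667 Ha
mu_z = -1.894 D
```

The sign follows the scan convention: the less electronegative atom sits
at the origin, the bond is stretched along +z, so negative μ_z means
H⁺F⁻ polarity.  The same pipeline runs from the shell:

```bash
paircc dipole --method oo-pccd-lccd --basis cc-pvdz --diatomic H F 0.917
paircc scan --method oo-pccd --basis aug-cc-pvtz --diatomic H F \
       --scan 1.10:1.45:0.05 --out hf_scan.csv
```

`paircc scan` writes the dipole-moment surface as CSV
(r_angstrom, mu_z_debye, converged) and a JSON report with the interior
maximum of |μ_z(r)| refined by a three-point quadratic fit — for HF this
"turning point" is the spectroscopically relevant feature of the surface.

## Layout

- `paircc.integrals` — McMurchie–Davidson engine, basis sets (text files),
  Cholesky decomposition, `AOIntegralSet`
- `paircc.scf` — restricted HF, Pipek–Mezey localization
- `paircc.mo` — AO→MO transforms, frozen-core folding, `MOIntegralSet`
- `paircc.pccd` / `paircc.oopccd` — pair amplitudes, Λ, response RDMs;
  orbital optimization
- `paircc.lcc` — linearized CC corrections from one oracle-certified term
  list (residual, Λ′ and density are mechanical transposes of it)
- `paircc.properties` — dipoles, finite-field oracle, DMS scans, MUE/RMSE
- `paircc.oracles` — determinant-space FCI/DOCI and projection checks
- `paircc.fcidump`, `paircc.cli`, `paircc.io_hdf5` — I/O and the driver

`docs/methods.md` documents the models, numerics and limitations.
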