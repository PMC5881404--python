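# Methods

## Model

`gausspb` implements a surface-free implicit-solvent model. Each atom is
an isotropic Gaussian density `ρ_i(r) = exp(−|r−r_i|²/(σ²R_i²))` with
`R_i` the atomic radius; atomic densities combine by the survival
product `ρ_mol = 1 − Π(1 − ρ_i)`, which behaves like a soft union of
spheres (saturates at 1, never double-counts overlap); and the local
dielectric is the linear blend `ε = ρ_mol ε_in + (1 − ρ_mol) ε_out`.
The model's assumptions: solute polarizability is homogeneous (one
ε_in), solvent is a structureless continuum whose accessibility tracks
atomic packing, and the smooth ε profile stands in for both side-chain
flexibility and partially immobilized interfacial water.

Mobile ions see no exclusion surface. Each species carries a Born
transfer penalty `ΔG(r) = (N_A z²e²/8πε₀r₀)(1/ε(r) − 1/ε_out)`,
evaluated from CODATA constants, positive wherever ε < ε_out. The sign
is chosen so that `exp(−ΔG/RT)` suppresses ions in low-dielectric
regions, which is the physically meaningful direction for a desolvation
penalty; the opposite sign (which would pull ions into the solute) is
selectable as `convention="attractive"` for auditing only. In the PB
exponent both the electrostatic energy `−z e φ` and the penalty are
divided by RT; they are both energies and no other reading is
dimensionally consistent.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| σ | 0.93 | – | Gaussian spread relative to atomic radius; value from published parameterizations against hydration energies and pKa shifts. Treated as a default, not refit. |
| ε_in | 2.0 | – | solute reference dielectric (electronic polarization only) |
| ε_out | 80.0 | – | bulk water at 298 K |
| cutoff | 3 | ×σR_i | density truncated to exactly 0 beyond; neglected density < e⁻⁹ ≈ 1.2×10⁻⁴, so the per-atom dielectric error is < e⁻⁹(ε_out−ε_in) ≈ 0.01 |
| grid spacing | 0.5 | Å | finite-difference resolution (0.25 for tight energy work) |
| box margin | max(40% extent, 10 Å) | per side | solvent shell around the solute bounding box; the 10 Å floor keeps single-atom toys properly solvated |
| T | 298.15 | K | temperature (RT = 0.5925 kcal/mol) |
| ion r₀ | 2.0 | Å | Born radius per species (no standard tabulation exists; configurable) |
| SOR relaxation ω | 1.9 | – | over-relaxation factor |
| tolerance | 10⁻⁶ | kT/e | max potential change per sweep at convergence |

The truncation distance scales with the atom (`3σR_i`, not 3σ in
absolute Å): this keeps the relative neglected density identical for
every atom size and makes the far-field dielectric exactly ε_out beyond
every atom's support — a property several tests rely on.

## Discretization and solver

Potentials are in kT/e, lengths in Å, charges in e, energies in
kcal/mol, with the Coulomb constant 332.0637 kcal·Å/(mol·e²) (the
DelPhi/APBS convention; it makes the closed-form oracles one-liners).
The PDE is discretized flux-conservatively on a uniform node-centered
grid: the 7-point stencil uses the dielectric at the six cell-face
midpoints, obtained by *direct evaluation* of the Gaussian model at
those points rather than by averaging node values — averaging would
smooth the very profile the model defines. Fixed charges are spread to
the 8 surrounding nodes with trilinear weights (total charge conserved
to 10⁻⁹ e).

The linear system is solved by checkerboard (red–black) SOR, fully
vectorized; convergence is declared when the largest potential change
in a sweep falls below the tolerance, and 50 consecutive sweeps of
growing change raise a divergence error suggesting a smaller ω. The
linearized salt mode adds a position-dependent diagonal screening
`4πC h² Σ z² c λ(r)` with `λ = exp(−ΔG_penalty/RT)` plus the matching
constant source (species with unequal penalties do not cancel); the
nonlinear mode lags the full Boltzmann source one sweep and damps its
update by 0.6, with the working potential clipped to ±50 kT/e inside
the exponential for robustness at molar salt. Dirichlet boundaries are
either grounded (zero) or the sum of screened monopole potentials
`C q exp(−κd)/(ε_out d)` over all grid charges (the default); for
spherically symmetric test cases the monopole boundary is exact, which
is what lets modest boxes reproduce closed forms tightly.

Polar solvation energy uses the standard two-solve reaction-field
scheme on one grid: solvated map versus uniform-ε_in reference,
`ΔG = ½ Σ q_i [φ_solv(r_i) − φ_ref(r_i)]` with trilinear interpolation
at atom centers; the grid self-energy cancels between the solves.
Binding energies difference three such energies on a single common grid
sized for the complex, so regridding noise cannot masquerade as an
interaction.

## Numerical behavior worth knowing

- **Sharp-map Born ion.** The energy converges to the analytic Born
  value, but the error is dominated by how the spherical boundary
  quantizes onto cell faces. When the sphere radius is a whole number
  of cells (R = 2 Å at h = 1.0/0.5/0.25) that quantization error
  *oscillates* between refinement levels; with incommensurate spacings
  (1.2/0.6/0.3) the improvement is monotone (measured 4.3% → 2.9% →
  1.5%). Refinement studies here use incommensurate sequences.
- **Gaussian-map Born ion.** The smooth cavity solvates *harder* than
  the sharp one, not weaker: ε(r) already rises inside r < R (ε ≈ 21 at
  1 Å for R = 2 Å, σ = 0.93), so solvent response sits closer to the
  charge. The exact continuum limit, from the radial Gauss-law
  quadrature `ΔG = (C q²/2) ∫ (1/ε(r) − 1/ε_in) r⁻² dr`, is
  −433 kcal/mol for the +1e, R = 2 Å toy versus −40.5 for the sharp
  sphere, and the grid solves approach it from above as h shrinks. The
  test suite asserts this bracketing with the quadrature as the
  independent oracle. Consequently absolute Gaussian-map solvation
  energies converge slowly in h and are far more negative than
  two-dielectric intuition suggests; differences (binding energies) are
  better behaved.
- **Non-interacting binding limit.** For net-charged partners the
  solvent-screened charge–charge reaction term decays only as 1/r
  (≈ +4.8 kcal/mol at 34 Å for ±1e) and is physics, not grid noise; the
  vanishing-ΔΔG limit is exhibited with neutral dipolar partners, whose
  cross term decays as 1/r³.

## Synthetic systems

The fixture generators define the study conditions: a single +1e, R = 2 Å
ion (Born oracle), a diatomic of 2 Å spheres (interface scans, hand-
evaluable midpoint), a pair of random 8 Å blobs of 1.8 Å atoms with
seeded uniform-in-sphere placement and net-neutral random charges
(binding-partner stand-in), and a 38 Å-thick atom slab (the typical
thickness of a POPC bilayer) for membrane-style dielectric profiles.
They reproduce packing geometry only — no chemistry, no protonation, no
conformational relaxation — so passing tests demonstrate correctness of
the field construction, solver and protocols, not predictive accuracy
on real complexes. Acceptance-style runs use grids up to 81³ nodes
(0.25 Å spacing), chosen as the resolution where the Born oracle sits
comfortably inside its tolerance.

## Known limitations

- Single resolution (no focusing, no multigrid); desk-scale systems.
- No nonpolar (cavity/dispersion) solvation term.
- No Stern layer or finite-ion-size correction; ion accessibility is
  purely energetic via the Born penalty.
- The bundled PDB parameter table is a minimal convenience (peptide
  backbone dipoles, formal side-chain charges, element radii), not a
  force field; serious work should supply PQR files parameterized
  externally.
- The traditional comparison surface is a probe-inflated van der Waals
  union, not a rolling-probe SES; it is used only as the sharp-boundary
  contrast, for which any sharp surface shows the same qualitative jump.
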