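# Methods

This note documents the models, numerical choices and limitations of
`remass`.  Units are AKMA-style throughout: Å, amu, kcal/mol, elementary
charge, fs (velocities in Å/fs), with R_c = k_B = 0.0019872041 kcal/(mol·K).

## The model system

The packaged solute is a 22-atom capped-alanine-like dipeptide
(CH3–CO–NH–CαH(CH3)–CO–NH–CH3) exposing the φ (C–N–Cα–C) and ψ (N–Cα–C–N)
backbone torsions, two carbonyl-oxygen acceptors and two amide-hydrogen
donors.  Its parameters are *generic packaged values*, not a published force
field: heavy-atom bond lengths and angle reference values are taken from the
idealised built geometry (so the built structure is an exact minimum of its
bonded terms), force constants are typical magnitudes (bonds
300 kcal/mol/Å², angles 45 kcal/mol/rad², φ/ψ cosine torsions ~1 kcal/mol,
amide torsions 8 kcal/mol with planar minima), and charges are small
group-neutral values.  The package studies the *methodology* — mass models,
tempering, step scaling — which is insensitive to the specific landscape;
nothing here should be read as a prediction for real alanine dipeptide.

Solvent is rigid three-site water (O–H 0.9572 Å, H–O–H 104.52°, charges
−0.834/+0.417 e, LJ on both O and H, modified-TIP3P-style constants), held
rigid by three distance constraints per molecule.  All twelve solute X–H
bonds are likewise constrained.  Waters are placed uniformly in the periodic
cube with random orientations, rejecting any placement that brings two atoms
within 1.5 Å (minimum image); a bounded retry loop raises an explicit
density error when the box cannot accommodate the request.

## Energies

Lennard-Jones uses the ε/r_min convention with Lorentz–Berthelot-style
combining (geometric ε, additive r_min/2); Coulomb is 332.0636·q_iq_j/r.
Both are multiplied by the standard cubic switching function on
[r_on, r_off] — the canonical window is 8–12 Å, scaled by (box/2)/12 for
boxes whose minimum-image radius is below 12 Å.  We switch the *potential*
(the common "switch" form); the reported energies and the analytically
propagated forces are exactly consistent, which is what the integrator and
the swap machinery require.  Electrostatics via switched cutoff rather than
Ewald summation is a deliberate fidelity deviation: it changes absolute
energies but none of the exchange or analysis machinery under test.
Exclusions: 1-2 and 1-3 pairs and all intra-water pairs; 1-4 and beyond
interact at full strength.

Every pair term is binned as solute–solute (E_p, which also receives all
bonded terms), solute–solvent (E_ps) or solvent–solvent (E_s); the
decomposition is exhaustive by construction and is verified against a
bucket-blind recomputation in the tests.  The PV term uses the fixed box
volume at 1 atm (1 atm·Å³ = 1.4584×10⁻⁵ kcal/mol); it is constant across
replicas in NVT and therefore cancels in swap exponents, but is carried so
the hybrid-enthalpy expression is complete.

## Mass models

* **HMR(k)**: every hydrogen mass ×k; each bonded heavy atom loses exactly
  the mass its hydrogens gained, so every molecule's mass is conserved to
  machine precision (asserted at 1e-9 amu).  k = 1 is the untouched
  reference.  The transform refuses factors that would leave a heavy atom no
  heavier than one of its own hydrogens (k = 4 on a methyl group: C would
  drop to 2.939 amu against 4.032 amu hydrogens).  Note that conservation
  fixes the HMR3 water oxygen at 15.9994 − 4×1.008 = 11.967 amu.
* **LW**: water H → 0.186496 amu, water O → 0.743963 amu (packaged TIP3P-F
  constants), giving a 1.116955 amu water, ~16× lighter than standard;
  the solute is untouched.
* **hLW**: the LW masses ×4 (water 4.46782 amu) plus HMR(k = 3) on the
  solute.  The solute factor 3 is the only choice consistent with hLW and
  HMR3 differing in water mass alone.

Transforms run only from a pristine topology (a provenance tag records the
applied model and blocks double application) and re-validate that all masses
stay positive.

## Dynamics

The integrator is the BAOAB splitting of underdamped Langevin dynamics
(γ default 5 ps⁻¹), chosen for its configurational accuracy at the large
steps the mass models enable; with γ = 0 and no constraints it reduces
exactly to velocity Verlet (verified to 1e-12).  Constraints are enforced by
matrix SHAKE/RATTLE: the RATTLE velocity projection solves the linear system
(J M⁻¹ Jᵀ)λ = −Jv exactly by a dense factorisation, and the SHAKE position
projection iterates Newton steps on the same matrix built from the reference
bond directions.  Couplings between constraints sharing an atom (rigid
waters, methyl groups) are therefore handled exactly each step, and
constraint residuals sit at machine precision.  The `rigid_scheme` option
(`rattle`/`settle`) is retained on the configuration for interface
completeness; both names map to this direct solver — a separate closed-form
three-site solver would change speed, not trajectories, at desk scale.

Velocities are initialised from a Maxwell–Boltzmann draw at the condition
temperature followed by constraint projection.  Degrees of freedom are
counted as 3N − (number of distance constraints), with no centre-of-mass
subtraction (Langevin does not conserve momentum).  Failure detection runs
every step: non-finite coordinates or energies, potential energy above a
per-atom threshold (default 1000 kcal/mol/atom), or a non-converging
constraint solve mark the step failed and truncate the trajectory — they are
recorded, never raised, because the stability scan consumes them as data.

Kinetic temperatures carry the expected O(δt²) discretisation bias (≈1–2 %
at 2 fs for this system); equipartition checks in the tests therefore run at
1 fs.

## REHT protocol

Conditions are exponential in solute temperature, T_m = T₀(T_max/T₀)^(m/(R−1)),
with the solvent ladder following the same rule on its own narrower range
(endpoints 310→350 K by default; T′₀ = T₀).  Each condition's step is
δt(T_m) = √(T₀/T_m)·δt₀ rounded to the *nearest* 0.1 fs — the only rounding
policy consistent with both 3.5→3.0 and 4.0→3.4 fs; flooring would give
2.9/3.3.  The number of integration steps between exchange attempts is fixed
at the base condition's value (2 ps at δt₀), so wall-clock intervals shrink
at hotter rungs.  Swap attempts alternate between even (0-1, 2-3, …) and odd
(1-2, 3-4, …) neighbour pairs; enthalpies for Δ are recomputed from the
cached energy decomposition of each replica's last step, with no extra force
evaluations.  On acceptance, replicas exchange conditions and velocities are
rescaled by √(T_new/T_old).  One root seed feeds fixed per-replica RNG
streams plus a dedicated swap stream, so runs are reproducible and replicas
are statistically independent.

Correctness rests on three tested properties: the replica↔condition map is a
permutation at all times; with β′ = β the swap exponent collapses
algebraically to the standard temperature-RE form (β_m−β_{m+1})(E′−E); and
on a discrete two-replica system the Gibbs-within-condition + Metropolis-swap
transition matrix leaves the product of Boltzmann distributions exactly
invariant (full enumeration).

## Stability scan

For each step size on a grid (default 2.0–6.0 fs in 0.2 fs increments) an
ensemble of short constant-T trajectories is run, reusing the same starting
structures and noise seeds across grid points and mass models to control
variance.  δt_f is the smallest step with at least one failure; δt_s is the
largest all-pass step.  The scan is validated against the closed-form linear
stability limit of a harmonic oscillator, ωδt < 2: failures must begin
within one grid step of 2/ω₀.  Published failure thresholds for specific
engines and force fields are not reproduction targets — δt_f depends on the
constraint algorithm and the force field — but the *protocol* and the
scaling arithmetic are exact.

## Analysis probes

* **Kinetic energy**: the Maxwell–Boltzmann reference for n_dof quadratic
  momentum terms is a gamma distribution, shape n_dof/2, scale R_cT; the
  deviation statistic is the RMSD between the sample histogram (200 bins
  over [0, max]) and the reference at bin centres.  The histogram binning is
  a package choice, so absolute RMSD magnitudes are comparable only within
  this package.  Instantaneous temperature is 2E_k/(n_dof·R_c).
* **PMF**: G = −R_cT·ln P over periodic 12° bins, shifted so min G = 0;
  empty bins get +∞ and are excluded from comparisons.  Basin states are
  carved per angle (1D): for each local minimum, G† is the lower of the two
  directional barrier maxima on the periodic profile, and the state is the
  connected bin set with G < G† − 0.5 kcal/mol.  Conventional
  alanine-dipeptide boundaries (Φ1: φ < −12° or φ > 168°; Φ2: 24° < φ <
  108°; Ψ1: ψ < −144° or ψ > 96°; Ψ2: −60° < ψ < 48°) ship as a reference
  configuration.
* **Hydration**: hydrogen bonds use |D−A| < 4 Å **and** ∠DHA > 150° (both
  strict, minimum image); g(r) normalises shell counts by the ideal-gas
  expectation at the bulk target density; the first solvation shell counts
  waters whose O is within 3.75 Å of any solute heavy atom, each water once.
* **RMSD**: optimal-superposition (Kabsch) RMSD with centroid removal and a
  proper rotation enforced; the residual is computed from the explicitly
  rotated coordinates rather than the e₀ − 2Σσ shortcut, which loses ~8
  digits to cancellation near zero.  An independent quaternion (Horn)
  implementation serves as the test oracle.
* **Equilibration**: P(state; t) is fit with a0 − a1·e^(−t/τ1) − a2·e^(−t/τ2)
  by bounded least squares (τ ∈ (0, 10× series length], three starting
  points, best residual wins, ties to the smaller τ1).  τ is the earliest
  time the *fit* reaches 95 % of P_eq, where P_eq is the supplied long-run
  population (preferred) or the fitted plateau a0 as fallback.  Reported
  times are rounded to 0.1 ps, and rounding happens only at reporting time:
  τ_σ = τ/σ and τ_σ,cor = (τ/σ)·slowdown are rounded independently from the
  unrounded chain (80.9/2 × 1.13 = 45.71 → 45.7, not 40.5 × 1.13 = 45.8).
  The slowdown factor expresses the measured cost of evaluating long-range
  interactions consistently across step sizes; it is an input, not something
  this package measures.

## Synthetic fixtures

The fixtures module generates data with known ground truth so every probe is
testable without dynamics: two-well von Mises mixtures on the circle with an
analytic log-density (inverse-Boltzmann oracle), exact gamma-distributed
kinetic energies, biexponential relaxation curves with Binomial(n_traj, p)/n_traj
counting noise, and uniform ideal-gas configurations (g(r) ≡ 1 oracle).
Default relaxation-recovery conditions are 300 trajectories recorded every
0.25 ps over ten τ2 — the frame-wise occupancy record a real analysis would
use; at this design the τ recovery is comfortably within 10 %.  What these
fixtures do *not* emulate: real force-field landscapes, correlated noise
within a trajectory, or solvent-mediated kinetics — passing tests show the
estimators are correct, not that any particular simulation is converged.

## Problem sizes

Desk-scale defaults keep everything on one CPU: 20–50 waters in 10–12 Å
boxes, 10–100 ps equilibration segments, stability scans of a few thousand
steps per grid point, 10⁴ kinetic-energy samples and 10⁶ synthetic angles.
These sizes were chosen so each statistical assertion retains clear power at
its stated tolerance.

## Known limitations

* NVT only: the isobaric ensemble (barostat) is out of scope; PV uses the
  fixed box volume.
* Switched-cutoff electrostatics, not Ewald/PME.
* No multiple-time-stepping; long-range-evaluation cadence enters only
  through the τ_σ,cor slowdown factor.
* The failure criterion (energy threshold / non-finite / constraint
  non-convergence) is an explicit approximation of an MD engine's crash; the
  mapping is heuristic by necessity.
* 1D state carving treats φ and ψ independently; a 2D basin analysis is not
  implemented.
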