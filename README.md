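# remass

Mass-accelerated replica exchange with hybrid tempering, at desk scale.

Two families of mass edits are widely used to speed up conformational
sampling in biomolecular molecular dynamics: **hydrogen mass repartitioning**
(HMR — multiply every hydrogen mass by *k* and subtract the gained mass from
the bonded heavy atom, conserving each molecule's mass, so that larger
integration steps become stable) and **light water** (LW / TIP3P-F — reduce
the water molecule from 18.0 to 1.117 amu to lower viscosity and accelerate
diffusion).  `remass` implements both, plus the hybrid **hLW** (4× the LW
water masses combined with HMR *k* = 3 on the solute), inside a complete
**replica exchange with hybrid tempering (REHT)** stack, and provides the
analysis probes needed to judge whether the mass edits preserve the physics
(kinetic-energy distributions, dihedral free-energy landscapes, hydration)
and whether they pay off (σ-scaled equilibration times).

The intended users are methods developers and students who want a
transparent, fully self-contained implementation of this machinery: the
package ships its own 22-atom capped-alanine-like solute and rigid
three-site water builder, so nothing has to be downloaded or parameterised.

## The core machinery

REHT runs *R* replicas at conditions *m* = 0…*R*−1, each a pair of
temperatures (*T*<sub>m</sub>, *T*′<sub>m</sub>): the solute is fully
tempered at *T*<sub>m</sub> while solvent-involving energies are scaled so
the solvent feels *T*′<sub>m</sub> ≤ *T*<sub>m</sub>, through the hybrid
enthalpy

```
H_m = E_p + (β'_m/β_m) (E_ps + E_s) + PV ,     β_m = 1/(R_c T_m)
```

with E_p, E_ps, E_s the solute–solute, solute–solvent and solvent–solvent
energies.  Adjacent replicas swap with probability ω = min(1, e^−Δ),

```
Δ = β_m [H_m(x_r') − H_m(x_r)] + β_{m+1} [H_{m+1}(x_r) − H_{m+1}(x_r')] .
```

Because HMR destabilises large steps at high temperature, each condition
integrates with a temperature-scaled step

```
δt(T_m) = sqrt(T_0 / T_m) · δt(T_0)   (rounded to 0.1 fs),
```

which holds the mean thermal displacement per step constant across the
ladder (4.0 fs at 310 K becomes 3.4 fs at 430 K).  Dynamics is BAOAB
Langevin with SHAKE/RATTLE bond constraints; an integrator-stability scan
sweeps δt to locate the smallest failing step δt_f.  Sampling efficiency is
compared on the σ-scaled clock, σ = δt_s/1 fs: an occupancy relaxation
P(state; t) is fit with a0 − a1 e^(−t/τ1) − a2 e^(−t/τ2), τ is the time the
fit reaches 95 % of the equilibrium population, and τ_σ = τ/σ (optionally
times a measured long-range-evaluation slowdown factor) is the
computational-effort verdict.

## Worked example

```python
from remass import build_toy_system, build_ladder, scale_step
from remass.mass_models import apply_lw, apply_hmr
from remass.analysis import scaled_times

top, state = build_toy_system(n_waters=50, box_edge=12.0, seed=1)
print(f"system: {top.n_atoms} atoms, {len(top.constraints)} rigid constraints")

lw = apply_lw(top)
print(f"LW water molecular mass: {lw.molecular_mass(1):.6f} amu "
      f"({top.molecular_mass(1) / lw.molecular_mass(1):.1f}x lighter)")

hmr3 = apply_hmr(top, 3)
print(f"HMR3 hydrogen mass: {[a.mass for a in hmr3.atoms if a.is_hydrogen][0]:.4f} amu")

lad = build_ladder(R=8, T0=310.0, Tmax=430.0, Tmax_solv=350.0, dt0=4.0)
for c in lad:
    print(f"m={c.index}  T={c.T:6.1f} K  T'={c.T_solv:6.1f} K  dt={c.dt:.1f} fs")

sigma, ts, tsc = scaled_times(tau=136.4, dt_s=4.0, slowdown=1.2)
print(f"tau=136.4 ps, sigma={sigma:.0f} -> tau_sigma={ts} ps, corrected {tsc} ps")
```

prints

```
system: 172 atoms, 162 rigid constraints
LW water molecular mass: 1.116955 amu (16.1x lighter)
HMR3 hydrogen mass: 3.0240 amu
m=0  T= 310.0 K  T'= 310.0 K  dt=4.0 fs
m=1  T= 324.8 K  T'= 315.4 K  dt=3.9 fs
m=2  T= 340.4 K  T'= 320.9 K  dt=3.8 fs
m=3  T= 356.7 K  T'= 326.6 K  dt=3.7 fs
m=4  T= 373.7 K  T'= 332.3 K  dt=3.6 fs
m=5  T= 391.6 K  T'= 338.1 K  dt=3.6 fs
m=6  T= 410.4 K  T'= 344.0 K  dt=3.5 fs
m=7  T= 430.0 K  T'= 350.0 K  dt=3.4 fs
tau=136.4 ps, sigma=4 -> tau_sigma=34.1 ps, corrected 40.9 ps
```

The solute temperatures are spaced exponentially from 310 to 430 K, the
solvent effective temperatures from 310 to 350 K, each rung's integration
step is √(T₀/T)-scaled, the LW transform reproduces the canonical 1.117 amu
water (≈16× lighter than standard), and the σ-scaled accounting turns a
136.4 ps equilibration at δt_s = 4 fs into a 34.1 ps effort (40.9 ps after
the ×1.2 long-range-evaluation correction).

A command-line interface mirrors the workflow
(`remass build / repartition / ladder / scan-dt / run / fixture`); try
`remass ladder --R 8 --dt0 4.0`.

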