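"""Physical constants and unit conversions (AKMA-style unit system).

Internal units: length Å, mass amu, energy kcal/mol, charge e, time fs,
temperature K.  Velocities are Å/fs.
"""

# Gas constant / Boltzmann constant in kcal/(mol K)
KB = 0.0019872041

# Coulomb prefactor: q_i q_j / r in e^2/Å -> kcal/mol
COULOMB = 332.0636

# (kcal/mol per amu) -> (Å/fs)^2 : acceleration conversion for F/m with
# F in kcal/mol/Å, m in amu, a in Å/fs^2.
ACC_CONV = 4.184e-4

# Kinetic energy: 0.5 * m[amu] * v[Å/fs]^2 / KE_CONV -> kcal/mol
KE_CONV = ACC_CONV

# 1 atm * Å^3 in kcal/mol
ATM_A3_TO_KCALMOL = 1.4584e-5

# --- Water geometry & parameters (rigid three-site, modified-TIP3P-style) ---
WATER_OH = 0.9572          # Å
WATER_ANGLE = 104.52       # degrees
WATER_HH = 1.5139006545247014  # 2*OH*sin(angle/2), Å

WATER_O_MASS = 15.9994
WATER_H_MASS = 1.0080
WATER_MASS = WATER_O_MASS + 2.0 * WATER_H_MASS   # 18.0154 amu

WATER_O_CHARGE = -0.834
WATER_H_CHARGE = 0.417
WATER_O_EPS = 0.1521       # kcal/mol
WATER_O_RMIN_HALF = 1.7682  # Å
WATER_H_EPS = 0.046
WATER_H_RMIN_HALF = 0.2245

# --- Light-water (TIP3P-F) masses, amu ---
LW_H_MASS = 0.186496
LW_O_MASS = 0.743963
LW_WATER_MASS = LW_O_MASS + 2.0 * LW_H_MASS      # 1.116955 amu

# hLW: light-water masses scaled by 4, solute repartitioned with k = 3
HLW_WATER_SCALE = 4.0
HLW_SOLUTE_K = 3
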