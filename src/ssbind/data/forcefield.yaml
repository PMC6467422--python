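# Force-field constants for the two-bead protein / three-bead nucleotide
# coarse-grained model.  All energies kcal/mol, lengths Å, charges in e.
# Version 1 — do not edit values in place; bump the version on any change.
version: 1

# Bonded terms (shared by protein and nucleic acid)
k_bonds: 100.0        # kcal mol^-1 Å^-2, harmonic
k_angles: 20.0        # kcal mol^-1 rad^-2, harmonic
k_dihedrals_protein: 1.0   # kcal mol^-1, K[1 - cos(dphi) - cos(3 dphi)]

# Nucleic-acid dihedral stiffness, per strand chemistry.
# base_sugar: B_i - S_i - S_{i+1} - B_{i+1};  backbone: P_i ... P_{i+3}
na_dihedrals:
  DNA: {base_sugar: 0.5, backbone: 0.3}
  RNA: {base_sugar: 1.5, backbone: 0.9}

# Non-bonded
k_contacts: 1.0       # kcal/mol, native-contact 12-10 well depth
k_repulsion: 1.0      # kcal/mol, (C_ij/r)^12 excluded volume
stack_r0: 3.6         # Å, reference distance for base-base and base-aromatic wells

# Excluded-volume radii (C_ij = sum of the two radii)
radii:
  CA: 1.9             # protein backbone bead
  CB: 1.5             # protein side-chain bead
  P: 3.7              # phosphate
  S: 3.7              # sugar
  B: 1.5              # nucleobase

# Reduced-unit energy scale: the thermostat temperature is given in
# reduced units (default 0.3) and converted to kcal/mol via this unit,
# k_BT = T_reduced * energy_unit.  Calibrated jointly with the strand
# templates so the working temperature reproduces the strand
# persistence lengths while keeping folded proteins stable.
energy_unit: 0.5

# Debye-Hückel electrostatics
coulomb_constant: 332.0637   # kcal Å mol^-1 e^-2
dielectric: 70.0
salt_mM: 10.0
temperature_K: 298.0         # used only to compute the Debye length
dh_ion_size: 4.0             # Å, a in B(kappa) = exp(kappa a)/(1 + kappa a)

# Cutoffs (dimensionless multipliers)
dh_cutoff_debye_lengths: 3.0   # DH truncated at 3 Debye lengths
lj_cutoff_factor: 3.0          # 12-10 wells truncated at 3 * (A or r0)
rep_cutoff_factor: 1.8         # repulsion truncated at 1.8 * C_ij ((1/1.8)^12 ~ 9e-4)
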