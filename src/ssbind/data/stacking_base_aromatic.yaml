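# Base-aromatic stacking well depths eps_B-AA (kcal/mol) between the
# side-chain (CB) bead of W/F/Y/H and a nucleobase bead.
#
# Provenance: solution-phase quantum-chemical stacked-dimer interaction
# energies for nucleobase-amino-acid pairs (Rutledge et al. style MP2/CCSD(T)
# calculations report magnitudes between 9.4 and 28.5 kJ/mol in water),
# rescaled by a factor of 0.15 into the coarse-grained energy scale and
# converted to kcal/mol.  The per-pair values below are SYNTHETIC
# reconstructions consistent with the published constraints (the exact
# dimer-by-dimer table is not reproduced here): stacking strength orders
# Phe < His ~ Tyr < Trp across residues and purine > pyrimidine across
# bases.  Uracil is set 9% below thymine (reported 8-10% weaker).
# Version 1.
version: 1
rescale_factor: 0.15
pairs:
  W: {A: 0.86, G: 1.02, C: 0.72, T: 0.79, U: 0.72}
  Y: {A: 0.61, G: 0.73, C: 0.52, T: 0.57, U: 0.52}
  H: {A: 0.59, G: 0.72, C: 0.50, T: 0.56, U: 0.51}
  F: {A: 0.41, G: 0.50, C: 0.34, T: 0.38, U: 0.35}
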