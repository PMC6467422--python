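# Idealized single-strand helical templates used to assign native bond
# lengths, angles and dihedrals of the three-bead nucleotide model.
# Geometry is the helical conformation a single strand adopts inside the
# duplex: B-like for DNA, A-like for RNA.  Beads are placed on a regular
# helix; per-bead cylindrical coordinates are (radius Å, phase deg, rise
# offset Å) relative to the nucleotide's phosphate.
#
# Radii, phases and rises are idealized fiber-model values; the helical
# twists sit within a few degrees of the canonical duplex values and
# were refined jointly with the reduced-unit energy scale so that the
# model's fixed dihedral stiffnesses reproduce the calibrated strand
# persistence lengths (see docs/methods.md).  Version 3.
version: 3
DNA:
  twist_deg: 36.0
  rise: 3.38
  beads:
    P: {radius: 8.9, phase_deg: 0.0, dz: 0.0}
    S: {radius: 6.7, phase_deg: 23.0, dz: 1.0}
    B: {radius: 2.0, phase_deg: 40.0, dz: 1.0}
RNA:
  twist_deg: 32.7
  rise: 2.81
  beads:
    P: {radius: 9.2, phase_deg: 0.0, dz: 0.0}
    S: {radius: 7.8, phase_deg: 20.0, dz: 1.5}
    B: {radius: 4.0, phase_deg: 50.0, dz: 1.8}
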