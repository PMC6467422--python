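# Base-base stacking well depths eps_B-B (kcal/mol) for consecutive
# intra-strand bases, order-independent (XY == YX).  Purines stack
# strongest, pyrimidines weakest; values rescaled to reproduce the
# experimental persistence length of poly-T ssDNA.
# Version 1.
version: 1
pairs:
  AA: 1.4
  TT: 1.0
  GG: 1.8
  CC: 1.4
  UU: 0.9
  AT: 1.4
  AG: 1.8
  AC: 1.5
  TG: 1.7
  TC: 1.4
  GC: 1.5
  AU: 1.3
  GU: 1.5
  CU: 1.3
  TU: 1.0   # never occurs in a single-chemistry strand; mean of TT/UU for completeness
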