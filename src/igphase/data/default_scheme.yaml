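# Default subclass-calling scheme, v1.
#
# The 12-nt identifiers are the CH1 positions 46-57 read by index read 1
# immediately 3' of the IgGcInd indexing-primer anchor (CH1 16-45):
#   IgG1        AAGAGCACCTCT   (codon 16 AAG = K, codon 19 TCT)
#   IgG3        AGGAGCACCTCT   (codon 16 AGG = R, codon 19 TCT)
#   IgG2/IgG4   AGGAGCACCTCC   (shared window; codon 19 TCC)
#   klMA        TTCTCGTGGAGA   (complement of the IgG1 identifier,
#                               engineered into the non-IgG reverse primer)
# IgG2 vs IgG4 is resolved by read-2 position 4, the complement of the
# third base of the first CH1 codon (GCC -> G -> IgG2, GCT -> A -> IgG4).
identifier_length: 12
identifiers:
  IgG1:
    - AAGAGCACCTCT
  IgG3:
    - AGGAGCACCTCT
  IgG24:
    - AGGAGCACCTCC
  klMA:
    - TTCTCGTGGAGA
igg_max_mismatch: 0
klma_max_mismatch: 1
discriminator:
  read: r2
  position: 4
  base_map:
    G: IgG2
    A: IgG4
  fallback: undetermined
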