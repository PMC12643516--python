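# RNA/RNA duplex nearest-neighbor parameters, version 1.
#
# Stacking free energies (kcal/mol, 37 C) for the ten unique Watson-Crick
# stacks plus G:U wobble stacks, following the standard published RNA
# nearest-neighbor set.  Indexing convention: stack[P][Q] is the energy of
# the helix fragment
#
#     5'-a b-3'
#     3'-c d-5'
#
# where P is the pair "ac" and Q is the pair "db" (second pair written
# 3'-base first, so that the table is symmetric under reading the helix
# from the other strand: stack[P][Q] == stack[Q][P]).
#
# Loop penalties are affine: a bulge of n unpaired bases on one strand
# costs bulge_open + bulge_ext*(n-1); an internal loop with a>=1 and b>=1
# unpaired bases on the two strands costs internal_open +
# internal_ext*(a+b-2).  No loop-size cap, no dangling-end terms, no
# duplex-initiation term (energies are pure hybridization energies, so a
# window with no stabilizing pairing scores 0).
version: 1
stack:
  CG: {CG: -2.4, GC: -3.3, GU: -2.1, UG: -1.4, AU: -2.1, UA: -2.1}
  GC: {CG: -3.3, GC: -3.4, GU: -2.5, UG: -1.5, AU: -2.2, UA: -2.4}
  GU: {CG: -2.1, GC: -2.5, GU: 1.3, UG: -0.5, AU: -1.4, UA: -1.3}
  UG: {CG: -1.4, GC: -1.5, GU: -0.5, UG: 0.3, AU: -0.6, UA: -1.0}
  AU: {CG: -2.1, GC: -2.2, GU: -1.4, UG: -0.6, AU: -0.9, UA: -1.3}
  UA: {CG: -2.1, GC: -2.4, GU: -1.3, UG: -1.0, AU: -1.3, UA: -1.1}
loops:
  bulge_open: 3.8
  bulge_ext: 0.5
  internal_open: 2.0
  internal_ext: 0.5
init: 0.0
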