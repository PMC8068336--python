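# Packaged CDS fixtures and diagnostic-variant configuration.
#
# The RAE2 fixture is a synthetic EPFL-like coding sequence engineered so
# that the full-length translation carries exactly six cysteines in the
# mature-peptide region and each haplotype-defining indel reproduces the
# documented cysteine class:
#   unedited          -> 6C (functional)
#   hap2 (6-bp del)   -> 6C, in-frame, two residues shorter (functional)
#   hap3 (1-bp del)   -> 4C, frameshift with premature stop between the
#                        4th and 5th cysteine codons
#   hap4 (2-bp del)   -> 7C, frameshift past the 6th cysteine adds one
#                        frame-shifted cysteine before the new stop
#   hap5 (2-bp del)   -> 7C, as hap4 at a distinct position
#   hap6 (1-bp ins)   -> 7C, as hap4
#
# The RAE1 fixture is a synthetic bHLH-like coding sequence with the
# reference G at CDS position 780; the diagnostic 1-bp deletion of that
# base frameshifts the tail and truncates the protein at a premature stop.
#
# Positions are 1-based CDS coordinates.  Deletion positions give the
# first deleted base; insertion positions give the base before which the
# new bases are inserted.

rae2:
  mature_start: 6
  cds: >-
    ATGCACAGACCGTCTTCCGACGGAATATGCGTCCTTTTGTACTTGTGCATAGCCGGCCGGATTTGCTTTAGC
    CCTCGGTCCTGCATTACGCGCGTCGTGACATTTTGCACTCAACCTACCATCTGCGTAGCGGTACTGCCTTTT
    TCCCCAATAGGAACGTGGGACCCTCCAATTGCTCGTCCTAAGGGAACAATTCGCATCAGTTTGGATGAGGTC
    TATAAATTTTAA
  edits:
    hap2: {op: del, pos: 88, length: 6}
    hap3: {op: del, pos: 92, length: 1}
    hap4: {op: del, pos: 130, length: 2}
    hap5: {op: del, pos: 139, length: 2}
    hap6: {op: ins, pos: 150, bases: A}

rae1:
  mature_start: 1
  cds: >-
    ATGATAGTGTCGCCCTGCGTGGTCAGTCTGTGGATCCGTCGTACTGCTACAACAGGCGCAGACGTTAACAGT
    TTCACGACAGGGTTGTTCTCGCGACGCGTATGGGATGGGATCCCCAGACCACATCAATGCGCACCTAAGCGC
    TGTCACTCGGCGGACTTAGGTCTGACTAGAAAAGCCGGTGCCGATAGTAAGCAACCGCCCGGTAGCGTTTGT
    TCCAGTGCACCTGTTGGGACGCGCAACCGACCATATTACTTGGCTCATCCGCTAAGTATCGTTTTGGAAGAT
    GAGAATCGGCAGATCATACTTCGGCTCAGCAGAGCGGCACAGCCACGCCCCCAGAGCGATGTGGGTTCTACC
    GTTCTCTTTGGAGCTATCCGTGCAAGAGATGGTCTAAATCAAAGCAAGTTGCTGGTGCGAATTTTCATAATT
    ATAGCGCCCTATAACTGCTCAAGGACGCAGCCGGTGGCATGTTTACGTCAATCAGATTATGGACTTAACGAG
    TGCGAGGTCACCGAAGGAGTACGCAAACCGGCTATCATCCAAAACGATATAAGAATTCACTCAGGTCACCAA
    CCAACACTAGGGCGCCCGCGAGGCTTGTGTGCTGCACCGCTACCGCGAGATTCTCATCTAATAGCCGAGTCC
    GGCGCTGTGAACATAGAGAGTGCCCTCGGAAACCGCACCGACGCCCACGGCAATCAGAAGGCGGTACTTAGA
    CACTTATTACGTTGTGTTAACACAGGCAGTCGCTCTGGTTTCACCTCCCGTTGGAAGACGGGCCAGCACAGA
    ACCGGATGGAGGCCAAACCCGGCTAAAGCAAAACTATTCAAGATAAATTCTATCCCTCGAGGCACGTGGGCC
    AAGTCGTTTAGGTTCGAGTATCATCGAAAGTATTAA
  edits:
    exon2_del: {op: del, pos: 780, length: 1}

# Diagnostic indel table used by the haplotyper to assign RAE2 haplotypes
# from normalized variants (mirrors the fixture edit positions above).
rae2_diagnostics:
  hap2: {kind: del, pos: 88, length: 6}
  hap3: {kind: del, pos: 92, length: 1}
  hap4: {kind: del, pos: 130, length: 2}
  hap5: {kind: del, pos: 139, length: 2}
  hap6: {kind: ins, pos: 150, length: 1}

rae1_diagnostics:
  exon2_del: {kind: del, pos: 780, length: 1}
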