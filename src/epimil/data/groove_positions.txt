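# HLA class II binding-groove residue positions used to build pseudo-sequences.
# Line 1: 15 alpha-chain positions; line 2: 19 beta-chain positions (1-based,
# mature-chain numbering).  These follow the polymorphic groove-lining residue
# selection popularised by the NetMHCIIpan family of tools; the file is data,
# not code, and may be edited to match any alternative groove definition.
9 11 22 24 31 52 53 58 59 61 65 66 68 72 73
9 11 13 26 28 30 47 57 67 70 71 74 77 78 81 85 86 89 90
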