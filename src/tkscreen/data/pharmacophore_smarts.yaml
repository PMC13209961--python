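# Versioned pharmacophore perception patterns (v1).
#
# HAC: N or O able to accept a hydrogen bond — excludes amide nitrogens,
#      positively charged atoms and aromatic N-H (pyrrole-type).
# HDO: N-H or O-H donors.
# POS/NEG: formally charged atoms at the fixed input protonation state
#      (no pKa model is applied).
# Aromatic (ARO) and hydrophobic (HPB) features are perceived from ring
# and fragment topology in code, not from SMARTS.
version: 1
hac:
  - "[N;!$([N+]);!$([NH]c);!$(NC=O);!$(N=O);X1,X2,X3;!$([nH])]"
  - "[n;+0;!$([nH]);X2]"
  - "[O;!$([O+]);!$([o])]"
  - "[o;+0;X2]"
hdo:
  - "[#7;!$([N+]);$([#7H1,#7H2,#7H3])]"
  - "[#8;$([#8H1])]"
pos:
  - "[+,++]"
neg:
  - "[-,--]"
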