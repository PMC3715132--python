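{
  "version": "1.1",
  "comment": "Retrosynthetic bond-cleavage rules. Each SMARTS identifies one cleavable acyclic bond between the two listed match-atom indices. Rules 1-11 are the classic retrosynthetic classes; phosphate_ester extends the scheme for phosphate-containing natural products.",
  "rules": [
    {"id": "amide", "smarts": "[CX3;!R](=[OX1])[NX3;!R]", "bond": [0, 2]},
    {"id": "ester", "smarts": "[CX3;!R](=[OX1])[OX2;!R][#6]", "bond": [0, 2]},
    {"id": "amine", "smarts": "[NX3;!R;!$([N][C,S]=[O,S,N]);!$([N]c)]([#6])[#6]", "bond": [0, 1]},
    {"id": "urea", "smarts": "[NX3][CX3](=[OX1])[NX3]", "bond": [0, 1]},
    {"id": "ether", "smarts": "[#6][OX2;!R;!$([O][#6]=O);!$([O]P)][#6]", "bond": [0, 1]},
    {"id": "olefin", "smarts": "[CX3;!R]=[CX3;!R]", "bond": [0, 1]},
    {"id": "quaternary_n", "smarts": "[NX4+][#6]", "bond": [0, 1]},
    {"id": "aromatic_n_aliphatic_c", "smarts": "[n][CX4;!R]", "bond": [0, 1]},
    {"id": "lactam_n_aliphatic_c", "smarts": "[NX3;R;$([N][C;R]=O)][CX4;!R]", "bond": [0, 1]},
    {"id": "biaryl", "smarts": "c-c", "bond": [0, 1]},
    {"id": "sulfonamide", "smarts": "[SX4](=[OX1])(=[OX1])[NX3]", "bond": [0, 3]},
    {"id": "phosphate_ester", "smarts": "[PX4;$(P=O)][OX2][#6]", "bond": [0, 1]}
  ]
}
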