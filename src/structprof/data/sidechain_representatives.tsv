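# one representative side-chain atom per residue type (fallback CA)
ALA	CB
ARG	CZ
ASN	CG
ASP	CG
CYS	SG
GLN	CD
GLU	CD
GLY	CA
HIS	CE1
ILE	CD1
LEU	CG
LYS	NZ
MET	SD
PHE	CZ
PRO	CG
SER	OG
THR	OG1
TRP	CE2
TYR	OH
VAL	CB
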