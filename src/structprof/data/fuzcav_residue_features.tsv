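# residue-level pharmacophoric features for cavity fingerprints
# features: donor acceptor positive negative aromatic aliphatic
ALA	aliphatic
ARG	donor,positive
ASN	donor,acceptor
ASP	acceptor,negative
CYS	donor,aliphatic
GLN	donor,acceptor
GLU	acceptor,negative
GLY	aliphatic
HIS	donor,acceptor,positive,aromatic
ILE	aliphatic
LEU	aliphatic
LYS	donor,positive
MET	aliphatic
PHE	aromatic,aliphatic
PRO	aliphatic
SER	donor,acceptor
THR	donor,acceptor
TRP	donor,aromatic
TYR	donor,acceptor,aromatic
VAL	aliphatic
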