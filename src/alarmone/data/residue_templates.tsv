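# Physicochemical atom-type templates, keyed by (residue, atom).
# flags: comma-separated subset of {donor,acceptor,aromatic,cationic,anionic,metal,hydrophobic}, or "-".
# Residue "*" rows are backbone/common atoms applied to any amino-acid residue.
# G4P = ppGpp (guanosine 3',5'-bis(diphosphate)); C1Z/0O2 = pppGpp (extra 5' gamma-phosphate).
# N9 is counted hydrogen-bond capable in the ligand census convention (all five guanine
# nitrogens), although it is glycosylated in the intact nucleotide.
residue	atom	flags
G4P	N1	donor,aromatic
G4P	C2	aromatic
G4P	N2	donor
G4P	N3	acceptor,aromatic
G4P	C4	aromatic
G4P	C5	aromatic
G4P	C6	aromatic
G4P	O6	acceptor
G4P	N7	acceptor,aromatic
G4P	C8	aromatic
G4P	N9	donor,aromatic
G4P	C1'	hydrophobic
G4P	C2'	hydrophobic
G4P	C3'	hydrophobic
G4P	C4'	hydrophobic
G4P	C5'	hydrophobic
G4P	O2'	donor,acceptor
G4P	O3'	acceptor
G4P	O4'	acceptor
G4P	O5'	acceptor
G4P	PA	-
G4P	O1A	acceptor,anionic
G4P	O2A	acceptor,anionic
G4P	O3A	acceptor
G4P	PB	-
G4P	O1B	acceptor,anionic
G4P	O2B	acceptor,anionic
G4P	O3B	acceptor,anionic
G4P	PC	-
G4P	O1C	acceptor,anionic
G4P	O2C	acceptor,anionic
G4P	O3C	acceptor
G4P	PD	-
G4P	O1D	acceptor,anionic
G4P	O2D	acceptor,anionic
G4P	O3D	acceptor,anionic
C1Z	N1	donor,aromatic
C1Z	C2	aromatic
C1Z	N2	donor
C1Z	N3	acceptor,aromatic
C1Z	C4	aromatic
C1Z	C5	aromatic
C1Z	C6	aromatic
C1Z	O6	acceptor
C1Z	N7	acceptor,aromatic
C1Z	C8	aromatic
C1Z	N9	donor,aromatic
C1Z	C1'	hydrophobic
C1Z	C2'	hydrophobic
C1Z	C3'	hydrophobic
C1Z	C4'	hydrophobic
C1Z	C5'	hydrophobic
C1Z	O2'	donor,acceptor
C1Z	O3'	acceptor
C1Z	O4'	acceptor
C1Z	O5'	acceptor
C1Z	PA	-
C1Z	O1A	acceptor,anionic
C1Z	O2A	acceptor,anionic
C1Z	O3A	acceptor
C1Z	PB	-
C1Z	O1B	acceptor,anionic
C1Z	O2B	acceptor,anionic
C1Z	O3B	acceptor
C1Z	PG	-
C1Z	O1G	acceptor,anionic
C1Z	O2G	acceptor,anionic
C1Z	O3G	acceptor,anionic
C1Z	PC	-
C1Z	O1C	acceptor,anionic
C1Z	O2C	acceptor,anionic
C1Z	O3C	acceptor
C1Z	PD	-
C1Z	O1D	acceptor,anionic
C1Z	O2D	acceptor,anionic
C1Z	O3D	acceptor,anionic
*	N	donor
*	O	acceptor
*	OXT	acceptor,anionic
*	C	hydrophobic
*	CA	hydrophobic
*	CB	hydrophobic
ARG	CG	hydrophobic
ARG	CD	hydrophobic
ARG	NE	donor,cationic
ARG	CZ	-
ARG	NH1	donor,cationic
ARG	NH2	donor,cationic
LYS	CG	hydrophobic
LYS	CD	hydrophobic
LYS	CE	hydrophobic
LYS	NZ	donor,cationic
ASP	CG	-
ASP	OD1	acceptor,anionic
ASP	OD2	acceptor,anionic
GLU	CG	hydrophobic
GLU	CD	-
GLU	OE1	acceptor,anionic
GLU	OE2	acceptor,anionic
ASN	CG	-
ASN	OD1	acceptor
ASN	ND2	donor
GLN	CG	hydrophobic
GLN	CD	-
GLN	OE1	acceptor
GLN	NE2	donor
SER	OG	donor,acceptor
THR	OG1	donor,acceptor
THR	CG2	hydrophobic
TYR	CG	aromatic
TYR	CD1	aromatic
TYR	CD2	aromatic
TYR	CE1	aromatic
TYR	CE2	aromatic
TYR	CZ	aromatic
TYR	OH	donor,acceptor
PHE	CG	aromatic
PHE	CD1	aromatic
PHE	CD2	aromatic
PHE	CE1	aromatic
PHE	CE2	aromatic
PHE	CZ	aromatic
TRP	CG	aromatic
TRP	CD1	aromatic
TRP	CD2	aromatic
TRP	NE1	donor,aromatic
TRP	CE2	aromatic
TRP	CE3	aromatic
TRP	CZ2	aromatic
TRP	CZ3	aromatic
TRP	CH2	aromatic
HIS	CG	aromatic
HIS	ND1	donor,acceptor,aromatic
HIS	CD2	aromatic
HIS	CE1	aromatic
HIS	NE2	donor,acceptor,aromatic
CYS	SG	donor,acceptor
MET	SD	acceptor
MET	CG	hydrophobic
MET	CE	hydrophobic
LEU	CG	hydrophobic
LEU	CD1	hydrophobic
LEU	CD2	hydrophobic
ILE	CG1	hydrophobic
ILE	CG2	hydrophobic
ILE	CD1	hydrophobic
VAL	CG1	hydrophobic
VAL	CG2	hydrophobic
PRO	CG	hydrophobic
PRO	CD	hydrophobic
HOH	O	donor,acceptor
MG	MG	metal
MN	MN	metal
ZN	ZN	metal
NA	NA	metal
K	K	metal
CA	CA	metal
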