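# ProtOr atomic group typing for the 20 standard amino acids.
# Group = element + total covalent connectivity + attached hydrogens
# (13 types); radius in Angstrom from the ProtOr united-group radius set
# (Tsai/Taylor/Chothia/Gerstein volume calculation scheme).
# Conventions: fixed HIS tautomer (ND1=N3H1, NE2=N3H0); carboxylate
# oxygens O1H0 (ionized); C-terminal OXT O2H1; N-terminal N typed as the
# residue's backbone N (single-assignment policy for determinism).
residue	atom	group	radius
ALA	N	N3H1	1.64
ALA	CA	C4H1	1.88
ALA	C	C3H0	1.61
ALA	O	O1H0	1.42
ALA	OXT	O2H1	1.46
ALA	CB	C4H3	1.88
ARG	N	N3H1	1.64
ARG	CA	C4H1	1.88
ARG	C	C3H0	1.61
ARG	O	O1H0	1.42
ARG	OXT	O2H1	1.46
ARG	CB	C4H2	1.88
ARG	CG	C4H2	1.88
ARG	CD	C4H2	1.88
ARG	NE	N3H1	1.64
ARG	CZ	C3H0	1.61
ARG	NH1	N3H2	1.64
ARG	NH2	N3H2	1.64
ASN	N	N3H1	1.64
ASN	CA	C4H1	1.88
ASN	C	C3H0	1.61
ASN	O	O1H0	1.42
ASN	OXT	O2H1	1.46
ASN	CB	C4H2	1.88
ASN	CG	C3H0	1.61
ASN	OD1	O1H0	1.42
ASN	ND2	N3H2	1.64
ASP	N	N3H1	1.64
ASP	CA	C4H1	1.88
ASP	C	C3H0	1.61
ASP	O	O1H0	1.42
ASP	OXT	O2H1	1.46
ASP	CB	C4H2	1.88
ASP	CG	C3H0	1.61
ASP	OD1	O1H0	1.42
ASP	OD2	O1H0	1.42
CYS	N	N3H1	1.64
CYS	CA	C4H1	1.88
CYS	C	C3H0	1.61
CYS	O	O1H0	1.42
CYS	OXT	O2H1	1.46
CYS	CB	C4H2	1.88
CYS	SG	S2H1	1.77
GLN	N	N3H1	1.64
GLN	CA	C4H1	1.88
GLN	C	C3H0	1.61
GLN	O	O1H0	1.42
GLN	OXT	O2H1	1.46
GLN	CB	C4H2	1.88
GLN	CG	C4H2	1.88
GLN	CD	C3H0	1.61
GLN	OE1	O1H0	1.42
GLN	NE2	N3H2	1.64
GLU	N	N3H1	1.64
GLU	CA	C4H1	1.88
GLU	C	C3H0	1.61
GLU	O	O1H0	1.42
GLU	OXT	O2H1	1.46
GLU	CB	C4H2	1.88
GLU	CG	C4H2	1.88
GLU	CD	C3H0	1.61
GLU	OE1	O1H0	1.42
GLU	OE2	O1H0	1.42
GLY	N	N3H1	1.64
GLY	CA	C4H2	1.88
GLY	C	C3H0	1.61
GLY	O	O1H0	1.42
GLY	OXT	O2H1	1.46
HIS	N	N3H1	1.64
HIS	CA	C4H1	1.88
HIS	C	C3H0	1.61
HIS	O	O1H0	1.42
HIS	OXT	O2H1	1.46
HIS	CB	C4H2	1.88
HIS	CG	C3H0	1.61
HIS	ND1	N3H1	1.64
HIS	CD2	C3H1	1.76
HIS	CE1	C3H1	1.76
HIS	NE2	N3H0	1.64
ILE	N	N3H1	1.64
ILE	CA	C4H1	1.88
ILE	C	C3H0	1.61
ILE	O	O1H0	1.42
ILE	OXT	O2H1	1.46
ILE	CB	C4H1	1.88
ILE	CG1	C4H2	1.88
ILE	CG2	C4H3	1.88
ILE	CD1	C4H3	1.88
LEU	N	N3H1	1.64
LEU	CA	C4H1	1.88
LEU	C	C3H0	1.61
LEU	O	O1H0	1.42
LEU	OXT	O2H1	1.46
LEU	CB	C4H2	1.88
LEU	CG	C4H1	1.88
LEU	CD1	C4H3	1.88
LEU	CD2	C4H3	1.88
LYS	N	N3H1	1.64
LYS	CA	C4H1	1.88
LYS	C	C3H0	1.61
LYS	O	O1H0	1.42
LYS	OXT	O2H1	1.46
LYS	CB	C4H2	1.88
LYS	CG	C4H2	1.88
LYS	CD	C4H2	1.88
LYS	CE	C4H2	1.88
LYS	NZ	N4H3	1.64
MET	N	N3H1	1.64
MET	CA	C4H1	1.88
MET	C	C3H0	1.61
MET	O	O1H0	1.42
MET	OXT	O2H1	1.46
MET	CB	C4H2	1.88
MET	CG	C4H2	1.88
MET	SD	S2H0	1.77
MET	CE	C4H3	1.88
PHE	N	N3H1	1.64
PHE	CA	C4H1	1.88
PHE	C	C3H0	1.61
PHE	O	O1H0	1.42
PHE	OXT	O2H1	1.46
PHE	CB	C4H2	1.88
PHE	CG	C3H0	1.61
PHE	CD1	C3H1	1.76
PHE	CD2	C3H1	1.76
PHE	CE1	C3H1	1.76
PHE	CE2	C3H1	1.76
PHE	CZ	C3H1	1.76
PRO	N	N3H0	1.64
PRO	CA	C4H1	1.88
PRO	C	C3H0	1.61
PRO	O	O1H0	1.42
PRO	OXT	O2H1	1.46
PRO	CB	C4H2	1.88
PRO	CG	C4H2	1.88
PRO	CD	C4H2	1.88
SER	N	N3H1	1.64
SER	CA	C4H1	1.88
SER	C	C3H0	1.61
SER	O	O1H0	1.42
SER	OXT	O2H1	1.46
SER	CB	C4H2	1.88
SER	OG	O2H1	1.46
THR	N	N3H1	1.64
THR	CA	C4H1	1.88
THR	C	C3H0	1.61
THR	O	O1H0	1.42
THR	OXT	O2H1	1.46
THR	CB	C4H1	1.88
THR	OG1	O2H1	1.46
THR	CG2	C4H3	1.88
TRP	N	N3H1	1.64
TRP	CA	C4H1	1.88
TRP	C	C3H0	1.61
TRP	O	O1H0	1.42
TRP	OXT	O2H1	1.46
TRP	CB	C4H2	1.88
TRP	CG	C3H0	1.61
TRP	CD1	C3H1	1.76
TRP	CD2	C3H0	1.61
TRP	NE1	N3H1	1.64
TRP	CE2	C3H0	1.61
TRP	CE3	C3H1	1.76
TRP	CZ2	C3H1	1.76
TRP	CZ3	C3H1	1.76
TRP	CH2	C3H1	1.76
TYR	N	N3H1	1.64
TYR	CA	C4H1	1.88
TYR	C	C3H0	1.61
TYR	O	O1H0	1.42
TYR	OXT	O2H1	1.46
TYR	CB	C4H2	1.88
TYR	CG	C3H0	1.61
TYR	CD1	C3H1	1.76
TYR	CD2	C3H1	1.76
TYR	CE1	C3H1	1.76
TYR	CE2	C3H1	1.76
TYR	CZ	C3H0	1.61
TYR	OH	O2H1	1.46
VAL	N	N3H1	1.64
VAL	CA	C4H1	1.88
VAL	C	C3H0	1.61
VAL	O	O1H0	1.42
VAL	OXT	O2H1	1.46
VAL	CB	C4H1	1.88
VAL	CG1	C4H3	1.88
VAL	CG2	C4H3	1.88
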