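# Protonation templates: residue, heavy-atom name, hydrogen count,
# hybridization tag (sp3 | sp2 | water | none).
# The BACKBONE block applies to every standard amino acid; residue
# blocks add side-chain atoms and override backbone entries (GLY CA,
# PRO N).  Counts encode the pH-7 convention: Lys/Arg protonated,
# Asp/Glu deprotonated, His neutral with the proton on NE2.
# Chain termini are handled at run time: a terminal ammonium N gets 3 H
# (2 for Pro) and the terminal carboxylate O/OXT get none.

bondlength C 1.09
bondlength N 1.01
bondlength O 0.96
bondlength S 1.34

BACKBONE N 1 sp2
BACKBONE CA 1 sp3
BACKBONE C 0 none
BACKBONE O 0 none
BACKBONE OXT 0 none

ALA CB 3 sp3
ARG CB 2 sp3
ARG CG 2 sp3
ARG CD 2 sp3
ARG NE 1 sp2
ARG CZ 0 none
ARG NH1 2 sp2
ARG NH2 2 sp2
ASN CB 2 sp3
ASN CG 0 none
ASN OD1 0 none
ASN ND2 2 sp2
ASP CB 2 sp3
ASP CG 0 none
ASP OD1 0 none
ASP OD2 0 none
CYS CB 2 sp3
CYS SG 1 sp3
GLN CB 2 sp3
GLN CG 2 sp3
GLN CD 0 none
GLN OE1 0 none
GLN NE2 2 sp2
GLU CB 2 sp3
GLU CG 2 sp3
GLU CD 0 none
GLU OE1 0 none
GLU OE2 0 none
GLY CA 2 sp3
HIS CB 2 sp3
HIS CG 0 none
HIS ND1 0 none
HIS CD2 1 sp2
HIS CE1 1 sp2
HIS NE2 1 sp2
ILE CB 1 sp3
ILE CG1 2 sp3
ILE CG2 3 sp3
ILE CD1 3 sp3
LEU CB 2 sp3
LEU CG 1 sp3
LEU CD1 3 sp3
LEU CD2 3 sp3
LYS CB 2 sp3
LYS CG 2 sp3
LYS CD 2 sp3
LYS CE 2 sp3
LYS NZ 3 sp3
MET CB 2 sp3
MET CG 2 sp3
MET SD 0 none
MET CE 3 sp3
PHE CB 2 sp3
PHE CG 0 none
PHE CD1 1 sp2
PHE CD2 1 sp2
PHE CE1 1 sp2
PHE CE2 1 sp2
PHE CZ 1 sp2
PRO N 0 none
PRO CB 2 sp3
PRO CG 2 sp3
PRO CD 2 sp3
SER CB 2 sp3
SER OG 1 sp3
THR CB 1 sp3
THR OG1 1 sp3
THR CG2 3 sp3
TRP CB 2 sp3
TRP CG 0 none
TRP CD1 1 sp2
TRP CD2 0 none
TRP NE1 1 sp2
TRP CE2 0 none
TRP CE3 1 sp2
TRP CZ2 1 sp2
TRP CZ3 1 sp2
TRP CH2 1 sp2
TYR CB 2 sp3
TYR CG 0 none
TYR CD1 1 sp2
TYR CD2 1 sp2
TYR CE1 1 sp2
TYR CE2 1 sp2
TYR CZ 0 none
TYR OH 1 sp3
VAL CB 1 sp3
VAL CG1 3 sp3
VAL CG2 3 sp3

HOH O 2 water
WAT O 2 water
DOD O 2 water
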