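# CHARMM19-style polar-hydrogen nonbonded parameters (united-atom aliphatic
# carbons). This is an approximate reconstruction, not the distributed
# param19/toph19 files: van der Waals well depths and Rmin/2 follow the
# param19 atom classes; partial charges are simplified but reproduce the
# integer net charge of every standard residue (stated in the NET lines).
# Columns: residue atom type charge[e] epsilon[kcal/mol] rmin_half[A]
NET ALA +0.00
ALA  N     NH1   -0.35 0.2384 1.600
ALA  H     H     +0.25 0.0498 0.800
ALA  CA    CH1E  +0.10 0.0486 2.365
ALA  C     C     +0.55 0.1200 2.100
ALA  O     O     -0.55 0.1591 1.600
ALA  CB    CH3E  +0.00 0.1811 2.165
NET ARG +1.00
ARG  N     NH1   -0.35 0.2384 1.600
ARG  H     H     +0.25 0.0498 0.800
ARG  CA    CH1E  +0.10 0.0486 2.365
ARG  C     C     +0.55 0.1200 2.100
ARG  O     O     -0.55 0.1591 1.600
ARG  CB    CH2E  +0.00 0.1142 2.235
ARG  CG    CH2E  +0.00 0.1142 2.235
ARG  CD    CH2E  +0.10 0.1142 2.235
ARG  NE    NH1   -0.40 0.2384 1.600
ARG  HE    H     +0.30 0.0498 0.800
ARG  CZ    C     +0.50 0.1200 2.100
ARG  NH1   NC2   -0.45 0.2384 1.600
ARG  HH11  H     +0.35 0.0498 0.800
ARG  HH12  H     +0.35 0.0498 0.800
ARG  NH2   NC2   -0.45 0.2384 1.600
ARG  HH21  H     +0.35 0.0498 0.800
ARG  HH22  H     +0.35 0.0498 0.800
NET ASN +0.00
ASN  N     NH1   -0.35 0.2384 1.600
ASN  H     H     +0.25 0.0498 0.800
ASN  CA    CH1E  +0.10 0.0486 2.365
ASN  C     C     +0.55 0.1200 2.100
ASN  O     O     -0.55 0.1591 1.600
ASN  CB    CH2E  +0.00 0.1142 2.235
ASN  CG    C     +0.55 0.1200 2.100
ASN  OD1   O     -0.55 0.1591 1.600
ASN  ND2   NH2   -0.60 0.2384 1.600
ASN  HD21  H     +0.30 0.0498 0.800
ASN  HD22  H     +0.30 0.0498 0.800
NET ASP -1.00
ASP  N     NH1   -0.35 0.2384 1.600
ASP  H     H     +0.25 0.0498 0.800
ASP  CA    CH1E  +0.10 0.0486 2.365
ASP  C     C     +0.55 0.1200 2.100
ASP  O     O     -0.55 0.1591 1.600
ASP  CB    CH2E  -0.16 0.1142 2.235
ASP  CG    C     +0.36 0.1200 2.100
ASP  OD1   OC    -0.60 0.6469 1.600
ASP  OD2   OC    -0.60 0.6469 1.600
NET CYS +0.00
CYS  N     NH1   -0.35 0.2384 1.600
CYS  H     H     +0.25 0.0498 0.800
CYS  CA    CH1E  +0.10 0.0486 2.365
CYS  C     C     +0.55 0.1200 2.100
CYS  O     O     -0.55 0.1591 1.600
CYS  CB    CH2E  +0.19 0.1142 2.235
CYS  SG    SH1E  -0.44 0.0430 1.890
CYS  HG    H     +0.25 0.0498 0.800
NET GLN +0.00
GLN  N     NH1   -0.35 0.2384 1.600
GLN  H     H     +0.25 0.0498 0.800
GLN  CA    CH1E  +0.10 0.0486 2.365
GLN  C     C     +0.55 0.1200 2.100
GLN  O     O     -0.55 0.1591 1.600
GLN  CB    CH2E  +0.00 0.1142 2.235
GLN  CG    CH2E  +0.00 0.1142 2.235
GLN  CD    C     +0.55 0.1200 2.100
GLN  OE1   O     -0.55 0.1591 1.600
GLN  NE2   NH2   -0.60 0.2384 1.600
GLN  HE21  H     +0.30 0.0498 0.800
GLN  HE22  H     +0.30 0.0498 0.800
NET GLU -1.00
GLU  N     NH1   -0.35 0.2384 1.600
GLU  H     H     +0.25 0.0498 0.800
GLU  CA    CH1E  +0.10 0.0486 2.365
GLU  C     C     +0.55 0.1200 2.100
GLU  O     O     -0.55 0.1591 1.600
GLU  CB    CH2E  +0.00 0.1142 2.235
GLU  CG    CH2E  -0.16 0.1142 2.235
GLU  CD    C     +0.36 0.1200 2.100
GLU  OE1   OC    -0.60 0.6469 1.600
GLU  OE2   OC    -0.60 0.6469 1.600
NET GLY +0.00
GLY  N     NH1   -0.35 0.2384 1.600
GLY  H     H     +0.25 0.0498 0.800
GLY  CA    CH2E  +0.10 0.1142 2.235
GLY  C     C     +0.55 0.1200 2.100
GLY  O     O     -0.55 0.1591 1.600
NET HIS -0.00
HIS  N     NH1   -0.35 0.2384 1.600
HIS  H     H     +0.25 0.0498 0.800
HIS  CA    CH1E  +0.10 0.0486 2.365
HIS  C     C     +0.55 0.1200 2.100
HIS  O     O     -0.55 0.1591 1.600
HIS  CB    CH2E  +0.00 0.1142 2.235
HIS  CG    C     +0.10 0.1200 2.100
HIS  ND1   NH1   -0.40 0.2384 1.600
HIS  HD1   H     +0.30 0.0498 0.800
HIS  CD2   CR1E  +0.10 0.1200 2.100
HIS  CE1   CR1E  +0.30 0.1200 2.100
HIS  NE2   NR    -0.40 0.2384 1.600
NET ILE +0.00
ILE  N     NH1   -0.35 0.2384 1.600
ILE  H     H     +0.25 0.0498 0.800
ILE  CA    CH1E  +0.10 0.0486 2.365
ILE  C     C     +0.55 0.1200 2.100
ILE  O     O     -0.55 0.1591 1.600
ILE  CB    CH1E  +0.00 0.0486 2.365
ILE  CG1   CH2E  +0.00 0.1142 2.235
ILE  CG2   CH3E  +0.00 0.1811 2.165
ILE  CD1   CH3E  +0.00 0.1811 2.165
NET LEU +0.00
LEU  N     NH1   -0.35 0.2384 1.600
LEU  H     H     +0.25 0.0498 0.800
LEU  CA    CH1E  +0.10 0.0486 2.365
LEU  C     C     +0.55 0.1200 2.100
LEU  O     O     -0.55 0.1591 1.600
LEU  CB    CH2E  +0.00 0.1142 2.235
LEU  CG    CH1E  +0.00 0.0486 2.365
LEU  CD1   CH3E  +0.00 0.1811 2.165
LEU  CD2   CH3E  +0.00 0.1811 2.165
NET LYS +1.00
LYS  N     NH1   -0.35 0.2384 1.600
LYS  H     H     +0.25 0.0498 0.800
LYS  CA    CH1E  +0.10 0.0486 2.365
LYS  C     C     +0.55 0.1200 2.100
LYS  O     O     -0.55 0.1591 1.600
LYS  CB    CH2E  +0.00 0.1142 2.235
LYS  CG    CH2E  +0.00 0.1142 2.235
LYS  CD    CH2E  +0.00 0.1142 2.235
LYS  CE    CH2E  +0.25 0.1142 2.235
LYS  NZ    NH3   -0.30 0.2384 1.600
LYS  HZ1   H     +0.35 0.0498 0.800
LYS  HZ2   H     +0.35 0.0498 0.800
LYS  HZ3   H     +0.35 0.0498 0.800
NET MET +0.00
MET  N     NH1   -0.35 0.2384 1.600
MET  H     H     +0.25 0.0498 0.800
MET  CA    CH1E  +0.10 0.0486 2.365
MET  C     C     +0.55 0.1200 2.100
MET  O     O     -0.55 0.1591 1.600
MET  CB    CH2E  +0.00 0.1142 2.235
MET  CG    CH2E  +0.06 0.1142 2.235
MET  SD    S     -0.12 0.0430 1.890
MET  CE    CH3E  +0.06 0.1811 2.165
NET PHE +0.00
PHE  N     NH1   -0.35 0.2384 1.600
PHE  H     H     +0.25 0.0498 0.800
PHE  CA    CH1E  +0.10 0.0486 2.365
PHE  C     C     +0.55 0.1200 2.100
PHE  O     O     -0.55 0.1591 1.600
PHE  CB    CH2E  +0.00 0.1142 2.235
PHE  CG    C     +0.00 0.1200 2.100
PHE  CD1   CR1E  +0.00 0.1200 2.100
PHE  CD2   CR1E  +0.00 0.1200 2.100
PHE  CE1   CR1E  +0.00 0.1200 2.100
PHE  CE2   CR1E  +0.00 0.1200 2.100
PHE  CZ    CR1E  +0.00 0.1200 2.100
NET PRO +0.00
PRO  N     N     -0.20 0.2384 1.600
PRO  CA    CH1E  +0.10 0.0486 2.365
PRO  C     C     +0.55 0.1200 2.100
PRO  O     O     -0.55 0.1591 1.600
PRO  CD    CH2E  +0.10 0.1142 2.235
NET SER +0.00
SER  N     NH1   -0.35 0.2384 1.600
SER  H     H     +0.25 0.0498 0.800
SER  CA    CH1E  +0.10 0.0486 2.365
SER  C     C     +0.55 0.1200 2.100
SER  O     O     -0.55 0.1591 1.600
SER  CB    CH2E  +0.25 0.1142 2.235
SER  OG    OH1   -0.65 0.1591 1.600
SER  HG    H     +0.40 0.0498 0.800
NET THR +0.00
THR  N     NH1   -0.35 0.2384 1.600
THR  H     H     +0.25 0.0498 0.800
THR  CA    CH1E  +0.10 0.0486 2.365
THR  C     C     +0.55 0.1200 2.100
THR  O     O     -0.55 0.1591 1.600
THR  CB    CH1E  +0.25 0.0486 2.365
THR  OG1   OH1   -0.65 0.1591 1.600
THR  HG1   H     +0.40 0.0498 0.800
THR  CG2   CH3E  +0.00 0.1811 2.165
NET TRP +0.00
TRP  N     NH1   -0.35 0.2384 1.600
TRP  H     H     +0.25 0.0498 0.800
TRP  CA    CH1E  +0.10 0.0486 2.365
TRP  C     C     +0.55 0.1200 2.100
TRP  O     O     -0.55 0.1591 1.600
TRP  CB    CH2E  +0.00 0.1142 2.235
TRP  CG    C     +0.00 0.1200 2.100
TRP  CD1   CR1E  +0.00 0.1200 2.100
TRP  CD2   C     +0.00 0.1200 2.100
TRP  NE1   NH1   -0.30 0.2384 1.600
TRP  HE1   H     +0.30 0.0498 0.800
TRP  CE2   C     +0.00 0.1200 2.100
TRP  CE3   CR1E  +0.00 0.1200 2.100
TRP  CZ2   CR1E  +0.00 0.1200 2.100
TRP  CZ3   CR1E  +0.00 0.1200 2.100
TRP  CH2   CR1E  +0.00 0.1200 2.100
NET TYR +0.00
TYR  N     NH1   -0.35 0.2384 1.600
TYR  H     H     +0.25 0.0498 0.800
TYR  CA    CH1E  +0.10 0.0486 2.365
TYR  C     C     +0.55 0.1200 2.100
TYR  O     O     -0.55 0.1591 1.600
TYR  CB    CH2E  +0.00 0.1142 2.235
TYR  CG    C     +0.00 0.1200 2.100
TYR  CD1   CR1E  +0.00 0.1200 2.100
TYR  CD2   CR1E  +0.00 0.1200 2.100
TYR  CE1   CR1E  +0.00 0.1200 2.100
TYR  CE2   CR1E  +0.00 0.1200 2.100
TYR  CZ    C     +0.25 0.1200 2.100
TYR  OH    OH1   -0.65 0.1591 1.600
TYR  HH    H     +0.40 0.0498 0.800
NET VAL +0.00
VAL  N     NH1   -0.35 0.2384 1.600
VAL  H     H     +0.25 0.0498 0.800
VAL  CA    CH1E  +0.10 0.0486 2.365
VAL  C     C     +0.55 0.1200 2.100
VAL  O     O     -0.55 0.1591 1.600
VAL  CB    CH1E  +0.00 0.0486 2.365
VAL  CG1   CH3E  +0.00 0.1811 2.165
VAL  CG2   CH3E  +0.00 0.1811 2.165
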