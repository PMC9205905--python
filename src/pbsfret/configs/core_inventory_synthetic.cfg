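; Pentacylindrical allophycocyanin core assembly map -- SYNTHETIC placeholder chain IDs.
; This file carries the published subunit inventory of the T. vulcanus PBS core
; (38 ApcA, 40 ApcB, 6 ApcC, 2 ApcD, 2 ApcE, 2 ApcF across cylinders A, A', B, C, C'),
; but the chain IDs below are placeholders: the deposited-entry chain-ID-to-cylinder
; correspondence is not printed in the text, so before use with a downloaded model the
; left-hand chain IDs must be replaced by the deposition's own chain IDs (taken from its
; struct_asym/entity annotations). ApcD placement is tentative in the deposited model
; and is flagged as such automatically.

[ligands]
codes = CYC
conjugated_atoms = C4A CHB C1B C2B C3B C4B NB CHC C1C C2C C3C C4C NC CHD C1D
dipole_sign_reference = C4A C1D

[chains.A]
AA = A 1 ApcD 1
AB = A 1 ApcA 2
AC = A 1 ApcA 3
AD = A 1 ApcB 1
AE = A 1 ApcB 2
AF = A 1 ApcB 3
AG = A 2 ApcA 1
AH = A 2 ApcA 2
AI = A 2 ApcA 3
AJ = A 2 ApcB 1
AK = A 2 ApcB 2
AL = A 2 ApcB 3
AM = A 3 ApcE 1
AN = A 3 ApcA 2
AO = A 3 ApcA 3
AP = A 3 ApcF 1
AQ = A 3 ApcB 2
AR = A 3 ApcB 3
AS = A 2 ApcC

[chains.Ap]
AT = A' 1 ApcD 1
AU = A' 1 ApcA 2
AV = A' 1 ApcA 3
AW = A' 1 ApcB 1
AX = A' 1 ApcB 2
AY = A' 1 ApcB 3
AZ = A' 2 ApcA 1
BA = A' 2 ApcA 2
BB = A' 2 ApcA 3
BC = A' 2 ApcB 1
BD = A' 2 ApcB 2
BE = A' 2 ApcB 3
BF = A' 3 ApcE 1
BG = A' 3 ApcA 2
BH = A' 3 ApcA 3
BI = A' 3 ApcF 1
BJ = A' 3 ApcB 2
BK = A' 3 ApcB 3
BL = A' 2 ApcC

[chains.B]
BM = B 1 ApcA 1
BN = B 1 ApcA 2
BO = B 1 ApcA 3
BP = B 1 ApcB 1
BQ = B 1 ApcB 2
BR = B 1 ApcB 3
BS = B 2 ApcA 1
BT = B 2 ApcA 2
BU = B 2 ApcA 3
BV = B 2 ApcB 1
BW = B 2 ApcB 2
BX = B 2 ApcB 3
BY = B 3 ApcA 1
BZ = B 3 ApcA 2
CA = B 3 ApcA 3
CB = B 3 ApcB 1
CC = B 3 ApcB 2
CD = B 3 ApcB 3
CE = B 4 ApcA 1
CF = B 4 ApcA 2
CG = B 4 ApcA 3
CH = B 4 ApcB 1
CI = B 4 ApcB 2
CJ = B 4 ApcB 3
CK = B 1 ApcC
CL = B 2 ApcC

[chains.C]
CM = C 1 ApcA 1
CN = C 1 ApcA 2
CO = C 1 ApcA 3
CP = C 1 ApcB 1
CQ = C 1 ApcB 2
CR = C 1 ApcB 3
CS = C 2 ApcA 1
CT = C 2 ApcA 2
CU = C 2 ApcA 3
CV = C 2 ApcB 1
CW = C 2 ApcB 2
CX = C 2 ApcB 3
CY = C 1 ApcC

[chains.Cp]
CZ = C' 1 ApcA 1
DA = C' 1 ApcA 2
DB = C' 1 ApcA 3
DC = C' 1 ApcB 1
DD = C' 1 ApcB 2
DE = C' 1 ApcB 3
DF = C' 2 ApcA 1
DG = C' 2 ApcA 2
DH = C' 2 ApcA 3
DI = C' 2 ApcB 1
DJ = C' 2 ApcB 2
DK = C' 2 ApcB 3
DL = C' 1 ApcC
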