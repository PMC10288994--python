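# Leukemia-relevant genes: fusions touching any of these are retained
# through the structural/annotation filters (whitelist rescue), because
# clinically relevant rearrangements are kept regardless of their
# promiscuity or structural class.  One symbol per line.
ABL1
AFF1
BCL9
BCL11B
BCR
CBFB
CRLF2
DEK
ELL
EP300
ERG
ETV6
FUS
HLF
JAK2
KDM5A
KMT2A
LMO1
LMO2
MEF2D
MLLT1
MLLT3
MLLT10
MYH11
NKX2-5
NUP98
NUP214
P2RY8
PAX5
PBX1
PML
RARA
RUNX1
RUNX1T1
SET
STIL
TAL1
TCF3
TLX1
TLX3
TRA
TRB
TRD
ZNF384
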