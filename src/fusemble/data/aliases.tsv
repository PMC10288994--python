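# gene symbol alias -> canonical symbol (HGNC), leukemia-relevant synonyms
MLL	KMT2A
MLL1	KMT2A
HRX	KMT2A
NKX2.5	NKX2-5
CSX	NKX2-5
AF4	AFF1
AF9	MLLT3
ENL	MLLT1
AF10	MLLT10
TEL	ETV6
AML1	RUNX1
ETO	RUNX1T1
CAN	NUP214
E2A	TCF3
TRD@	TRD
TRA@	TRA
IGH@	IGH
TCL5	TAL1
SCL	TAL1
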