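protein	direction	confidence	regulators
EIF4E	down	0.9783	up:miR-9
RAD50	down	0.9493	up:miR-9;up:miR-33b
STAT5A	down	0.9081	up:miR-18b;up:miR-33b
ESR1	down	0.8986	up:miR-9;up:miR-18b;up:miR-33b;up:miR-106a;up:miR-106b;down:miR-372
PXN	down	0.8986	up:miR-9
EIF4EBP1	down	0.8812	up:miR-18b
CTNNB1	down	0.8812	up:miR-33b
GYS1	down	0.8812	up:miR-106a;up:miR-106b;down:miR-372
MDM2	down	0.8812	up:miR-106a;up:miR-106b;down:miR-372
RPS6KA1	down	0.8812	up:miR-106a;up:miR-106b;down:miR-372
RPS6KA2	down	0.8812	up:miR-9;up:miR-33b;up:miR-106a;up:miR-106b;up:miR-518a-3p;down:miR-372
RPS6KA3	down	0.8812	up:miR-9;up:miR-18b;up:miR-33b;up:miR-106a;up:miR-106b;up:miR-518a-3p;down:miR-372
NDRG1	down	0.8341	up:miR-9;up:miR-18b
RAF1	up	0.9783	up:miR-106a
YWHAB	up	0.9493	up:miR-18b;up:miR-106a
CDKN1B	up	0.9014	up:miR-9
SRC	up	0.9014	up:miR-9
LCK	up	0.8986	up:miR-18b
RPS6KB1	up	0.8812	up:miR-33b
STMN1	up	0.8812	up:miR-9;up:miR-106a;up:miR-210
YWHAZ	up	0.8341	down:miR-372;up:miR-106a;up:miR-106b
BCL2L1	up	0.8043	up:miR-9;up:miR-106a;up:miR-106b
NRG1	up	0.8043	up:miR-18b
PARP1	up	0.8043	down:miR-372;up:miR-9;up:miR-33b;up:miR-106a;up:miR-106b
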