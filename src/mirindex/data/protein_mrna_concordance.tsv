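molecule	protein_direction	protein_confidence	gene_direction	gene_confidence	gene_assay
YWHAZ	up	0.834	up	0.917	microarray
BCL2L1	up	0.804	down	0.285	microarray
RAF1	up	0.978	up	0.571	microarray
EIF4E	down	0.978	up	0.548	microarray
ESR1	down	0.899	down	0.917	microarray
PARP1	up	0.804	down	NA	qpcr
RPS6KA1	down	0.881	down	0.833	microarray
STAT5A	down	0.908	down	0.548	microarray
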