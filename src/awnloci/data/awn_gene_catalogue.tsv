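name	chromosome	start	end	scope	source
RAE1	chr4	16731738	16735336	gene	An-1/RAE1 cloned awn gene
LABA1	chr4	25959399	25963504	gene	LABA1/An-2 cloned awn gene
RAE2	chr8	23998787	24000176	gene	RAE2/GAD1/GLA cloned awn gene
An7	chr5	.	.	chromosome	QTL, short arm of chromosome 5
An9	chr1	.	.	chromosome	QTL, chromosome 1
An10	chr1	.	.	chromosome	QTL, long arm of chromosome 1
qAWL2	chr2	.	.	chromosome	awn-length QTL, chromosome 2
RAE3	chr6	.	.	chromosome	unidentified awn locus, chromosome 6
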