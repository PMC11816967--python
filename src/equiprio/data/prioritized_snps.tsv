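# sha256:1e1094cc0dd56f72caf4e0b21135738644394b64199188f22bcc84552348ab65
gene_symbol	type	rs_id	marker_id	consequence	constrained	gerp	tf_binding	human_reg	mouse_reg	mirna
ACYP2	LD	rs397216526	(BIEC2_307086)	intron variant		-0.446		enhancer		
ACYP2	LD	rs69086544	(BIEC2_307086)	intron variant		-0.446		enhancer		
AHNAK	Marker	rs69004899	12-26376598-G-A	missense variant						
ALB	Marker	rs68643854	BIEC2_825788	intron variant	Yes	-0.108				
ALB	LD	rs68643900	(BIEC2_785750)	upstream gene variant		-3.12	Gain of TFBS			
ALDOA	Marker	rs69014980	BIEC2_215098	intron variant	Yes	-0.27				
ALDOA	Marker	rs782859809	13-20698094-G-C	intron variant		3.87	Loss of TFBS			
ASNS	Marker	rs69611459	BIEC2-860417	3' UTR variant						miR-329b
CS	LD	rs1143598220	(BIEC2_1184909)	intron variant					enhancer	
GOT1	Marker	rs68640585	BIEC2_13411	upstream gene variant, 5' UTR variant, intron variant		-1.05			enhancer	
MACROD1	Marker	rs68893372	BIEC2_195029	intron variant		-5.12		enhancer	enhancer	
MACROD1	Marker	rs68893379	BIEC2_195036	intron variant					enhancer	
MACROD1	Marker	rs69007205	BIEC2_195018	intron variant	Yes	-0.807			enhancer	
MTHFD1	Marker	rs69302674	BIEC2_632816	intron variant	Yes	-0.303				
MTHFD1	LD	rs782854427	(BIEC2_632813)	missense variant	Yes	-1.43				
MYL11	Marker	rs69065907	BIEC2_214942	upstream gene variant		-1.72	Gain of TFBS, Loss of TFBS, Score Change			
MYOM1	LD	rs1142180487	(BIEC2_1047070)	intron variant	Yes	0.206				
MYOM1	LD	rs1150182996	(BIEC2_1047100)	intron variant		2.04		enhancer		
MYOM1	LD	rs396225196	(BIEC2_1047096)	intron variant		0.623		enhancer		
MYOM1	Marker	rs68759950	BIEC2_1047096	intron variant		-0.836			enhancer	
PDLIM5	Marker	rs68623490	BIEC2_818877	intron variant	Yes	4.91				
PHGDH	LD	rs394992807	(BIEC2_908679)	intron variant					enhancer	
PHGDH	LD	rs395235076	(BIEC2_908679)	intron variant					enhancer	
PLIN1	Marker	rs397479732	CUHSNP00113433	missense variant		-0.63			enhancer	
PYGM	Marker	rs68895977	BIEC2_195234	upstream gene variant		0.644	Gain of TFBS			
RAVER2	Marker	rs69522601	BIEC2_978964	synonymous variant, 3' UTR variant	Yes	-4.36				miR-217, miR-509a-5p, miR-8924, miR-1388, miR-9065, miR-9124
RYR3	LD	rs1142172760	(BIEC2_65875)	intron variant		-8.78			enhancer	
RYR3	LD	rs1148992878	(BIEC2_65875)	intron variant					enhancer	
RYR3	Marker	rs68480423	BIEC2_66277	splice polypyrimidine tract variant, intron variant		-5.06				
SDHB	LD	rs68545902	BIEC2_471516	upstream gene variant, intron variant		-1.79	Score Change			
TNNT3	Marker	rs68882259	BIEC2_200114	downstream gene variant				enhancer		
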