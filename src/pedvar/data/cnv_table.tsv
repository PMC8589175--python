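table	pedigree	ethnicity	chrom	start	end	gene	zygosity	svtype	quoted_size	novelty	reference
3	RF.VI96.0210	Mexican	chr6	65994849	67582755	EYS	hom	DEL	1.6 Mb	novel	this_study
3	RF.277.0113	Pakistani	chr6	80205052	80315592	LCA5	hom	DEL	110 Kb	novel	this_study
3	RF.T.8.11	European_American	chr2	182456422	182479267	CERKL	comp_het	DEL	22.8 Kb	novel	this_study
3	C790	European_American	chr6	42643442	42676411	UBR2;PRPH2	het	DEL	33 Kb	novel	this_study
3	RF.M.0592	European_American	chr8	87616103	87623431	CNGB3	comp_het	DEL	7 Kb	novel	this_study
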