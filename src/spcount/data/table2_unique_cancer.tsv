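sn	uniprot_id	protein	abundance
1	Q13421	mesothelin isoform X1	L
2	Q6W4X9	mucin-6 (MUC6) isoform X1, partial	L
3	Q13438	protein OS-9 isoform X1	L
4	Q02413	desmoglein-1 preproprotein	VL
5	P68871	hemoglobin subunit beta	VL
6	O14773	tripeptidyl-peptidase 1 preproprotein	VL
7	Q86YZ3	hornerin	VL
8	P08697	alpha-2-antiplasmin isoform X6	VL
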