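accession	length	cancer_r1	cancer_r2	cancer_r3	fertile_r1	fertile_r2	fertile_r3
Q13421	622	12	10	14	0	0	0
Q6W4X9	2439	9	11	13	0	0	0
Q13438	667	15	12	12	0	0	0
Q02413	1049	3	4	2	0	0	0
P68871	147	5	6	4	0	0	0
O14773	563	2	3	2	0	0	0
Q86YZ3	2850	4	3	5	0	0	0
P08697	491	2	2	3	0	0	0
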