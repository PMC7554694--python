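OXPHOS_DEMO	toy oxidative-phosphorylation set	P28331	P22695	P25705	P31040	O75390
TCA_DEMO	toy tricarboxylic-acid-cycle set	O75390	P07954	P40926	Q99798	P50213
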