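set_name	member	sign
OXPHOS_DEMO	P28331	1
OXPHOS_DEMO	P22695	1
OXPHOS_DEMO	P25705	1
OXPHOS_DEMO	P31040	1
OXPHOS_DEMO	O75390	1
TCA_DEMO	O75390	1
TCA_DEMO	P07954	1
TCA_DEMO	P40926	1
TCA_DEMO	Q99798	1
TCA_DEMO	P50213	1
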