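dose	n_total	n_affected
0	50	1
5	50	1
20	50	0
60	50	2
180	50	11
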