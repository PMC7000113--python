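run_id	group	replicate
A_R1	A	1
A_R2	A	2
A_R3	A	3
B_R1	B	1
B_R2	B	2
B_R3	B	3
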