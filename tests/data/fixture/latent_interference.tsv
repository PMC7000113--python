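precursor_id	run_id	ms_level
P00001_p2	B_R1	1
P00002_p1	A_R1	1
P00003_p1	B_R2	1
P00004_p1	A_R2	1
P00005_p1	B_R1	1
P00005_p2	A_R2	1
P00009_p1	B_R2	1
P00010_p2	A_R3	1
P00011_p1	A_R1	1
P00011_p1	B_R1	1
P00012_p1	B_R1	1
P00013_p2	A_R2	1
P00013_p2	B_R3	1
P00015_p1	B_R3	1
P00017_p2	A_R2	1
P00018_p2	B_R2	1
P00019_p2	B_R1	1
P00020_p1	B_R1	1
P00001_p2	A_R1	2
P00001_p2	A_R3	2
P00002_p2	A_R3	2
P00004_p1	B_R2	2
P00004_p2	A_R3	2
P00005_p1	A_R2	2
P00008_p2	B_R1	2
P00010_p2	B_R3	2
P00010_p3	A_R1	2
P00012_p1	A_R1	2
P00013_p2	A_R2	2
P00013_p2	B_R2	2
P00013_p3	A_R3	2
P00015_p1	A_R3	2
P00016_p1	A_R3	2
P00016_p2	B_R3	2
P00019_p2	A_R2	2
P00020_p2	B_R1	2
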