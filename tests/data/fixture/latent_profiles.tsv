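protein_id	baseline_log2	A	B
P00001	12.046731	0	0
P00002	14.191761	0	1
P00003	13.525636	0	0
P00004	13.974798	0	0
P00005	12.720434	0	0
P00006	15.319097	0	0
P00007	15.166688	0	0
P00008	14.099046	0	0
P00009	15.690862	0	1
P00010	14.701264	0	0
P00011	12.711061	0	0
P00012	14.553126	0	1
P00013	12.561676	0	0
P00014	15.317675	0	1
P00015	13.925111	0	0
P00016	13.722706	0	0
P00017	12.978606	0	0
P00018	15.833812	0	0
P00019	13.768206	0	0
P00020	13.357508	0	1
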