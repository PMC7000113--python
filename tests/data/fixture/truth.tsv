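protein_id	is_changed	true_log2fc
P00001	False	
P00002	True	1.0
P00003	False	
P00004	False	
P00005	False	
P00006	False	
P00007	False	
P00008	False	
P00009	True	1.0
P00010	False	
P00011	False	
P00012	True	1.0
P00013	False	
P00014	True	1.0
P00015	False	
P00016	False	
P00017	False	
P00018	False	
P00019	False	
P00020	True	1.0
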