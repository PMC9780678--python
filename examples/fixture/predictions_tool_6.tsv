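compound_id	target_id	rank	score
C_0002	P42574	1	
C_0002	P22303	2	
C_0002	P05067	3	
C_0004	P22303	1	
C_0004	P42574	2	
C_0004	P05067	3	
C_0025	P22303	1	
C_0025	P05067	2	
C_0027	P05067	1	
C_0027	P42574	2	
C_0031	P22303	1	
C_0031	P42574	2	
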