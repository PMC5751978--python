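trait	lesr_mean	lesr_sd	line115S_mean	line115S_sd	line93S_mean	line93S_sd
SSE	9.19	2.56	31.01	4.50	28.31	3.98
DSE	3.34	1.48	11.67	2.06	10.81	3.02
SE	12.53	2.44	42.68	3.39	39.12	3.48
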