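plant_id	phenotype	InDel-1	RM6124	InDel-2	InDel-3	InDel-4	InDel-5	RM6868
R1	low	B	H	A	A	A	A	A
R2	low	H	H	A	A	A	A	A
R3	low	H	A	A	A	A	A	A
R4	low	A	A	A	A	A	A	H
R5	low	A	A	A	A	A	H	H
R6	low	A	A	A	A	A	H	B
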