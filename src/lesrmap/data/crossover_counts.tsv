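marker	n_single	n_double	n_plants
RM25179	79	14	464
RM25192	71	13	464
RM6124	11	0	464
RM6868	24	3	464
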