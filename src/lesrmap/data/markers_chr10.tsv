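name	chrom	pos	fwd_primer	rev_primer
InDel-1	chr10	12973374	ACCGTTCGTCTTATTCAAAA	ACCGTTCGTCTTATTCAAAA
RM6124	chr10	13525908	TCACGAAGGTGAGACTGACG	CCCATGAATCACCACCACC
InDel-2	chr10	13690353	GAACCACAAAACCAGACATT	TCAAAAATGCTGACTAGGCT
InDel-3	chr10	13814432	AATTTATGGCTATGTGTCGG	GCTAAACACTGCTTCGTTTT
InDel-4	chr10	13939718	TGTCCGAGTTTCTTCATTTT	GGGAGTACACCATCTTTCAA
InDel-5	chr10	14143271	CTGGAGGAACTGTCTCATTC	CATGCCTAGGCCTATCACTA
RM6868	chr10	14363911	TGAACATGCCGAGGAAGC	ATATAGAACCCAAAGCCCCC
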