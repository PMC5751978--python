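gene_id	pos	allele_93S	allele_lesr	allele_115S	variant_class	annotation
OS10g0403400	13691833	C	T	T	upstream	n/a
OS10g0403700	13707487	A	G	G	upstream	uncharacterized oxidoreductase
OS10g0404566	13784059	C	A	C	upstream;downstream	sucrose transporter
OS10g0404566	13784298	A	G	G	upstream;downstream	sucrose transporter
OS10g0406400	13897237	A	G	G	nonsynonymous(Asn-Asp)	mannan synthase
OS10g0406600	13905957	T	G	G	upstream	LYR motif containing protein
OS10g0406800	13919474	G	A	A	upstream	expressed protein
OS10g0406800	13919498	A	G	G	upstream	expressed protein
OS10g0407000	13935368	T	G	G	upstream	Pectinesterase
OS10g0407000	13935387	G	A	G	upstream	Pectinesterase
OS10g0407000	13935422	A	G	G	upstream	Pectinesterase
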