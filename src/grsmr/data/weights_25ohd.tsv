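rsid	chrom	pos	effect_allele	other_allele	eaf	beta	se	pvalue
rs4588	4	72618323	G	T	0.717	0.2469	0.0070	1.68e-263
rs116970203	11	14876718	G	A	0.975	0.4323	0.0209	2.29e-90
rs4423214	11	71173254	T	C	0.697	0.0998	0.0073	1.39e-40
rs10741657	11	14914878	A	G	0.415	0.0938	0.0065	8.76e-45
rs6013897	20	52742479	T	A	0.791	0.0658	0.0080	9.06e-16
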