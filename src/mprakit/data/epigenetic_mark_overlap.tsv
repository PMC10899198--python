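group	size	annotation_class	count
allele_specific_enhancers	27	promoter	1
allele_specific_enhancers	27	enhancer	16
allele_specific_enhancers	27	dnase	9
allele_specific_enhancers	27	protein_binding	2
general_enhancers	91	promoter	22
general_enhancers	91	enhancer	46
general_enhancers	91	dnase	37
general_enhancers	91	protein_binding	23
background	5094	promoter	856
background	5094	enhancer	2765
background	5094	dnase	1529
background	5094	protein_binding	616
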