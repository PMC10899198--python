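variant_id	chrom	pos	tf	score	fdr_bin
rs2746478	chr1	17015765	GLIS3	-0.8	lt0.05
rs2746478	chr1	17015765	ZIC5	-0.8	lt0.05
rs6689005	chr1	65375651	SREBF1	-0.8	lt0.05
rs6689005	chr1	65375651	EHF	-0.8	lt0.05
rs6689005	chr1	65375651	ELF1	-0.8	lt0.05
rs6689005	chr1	65375651	ELF4	-0.8	lt0.05
rs6689005	chr1	65375651	ERF	-0.8	lt0.05
rs6689005	chr1	65375651	ERG	-0.8	lt0.05
rs6689005	chr1	65375651	ETS1	-0.8	lt0.05
rs6689005	chr1	65375651	ETS2	-0.8	lt0.05
rs6689005	chr1	65375651	ETV1	-0.8	lt0.05
rs6689005	chr1	65375651	ETV2	-0.8	lt0.05
rs6689005	chr1	65375651	FLI1	-0.8	lt0.05
rs6689005	chr1	65375651	GABPA	-0.8	lt0.05
rs6689005	chr1	65375651	IKZF1	-0.8	lt0.05
rs6689005	chr1	65375651	STAT2	-0.8	lt0.05
rs16830920	chr2	134707896	HSF2	-0.8	lt0.05
rs3739034	chr2	134725811	EOMES	-0.8	lt0.05
rs3739034	chr2	134725811	GATA1	-0.8	lt0.05
rs3739034	chr2	134725811	GATA2	-0.8	lt0.05
rs3739034	chr2	134725811	GATA4	-0.8	lt0.05
rs3739034	chr2	134725811	GATA6	-0.8	lt0.05
rs6719061	chr2	232831175	PRDM14	-0.8	lt0.05
rs6719061	chr2	232831175	TRPS1	-0.8	lt0.05
rs812383	chr2	232872422	NKX3-2	-0.8	lt0.05
rs812383	chr2	232872422	TBX19	-0.8	lt0.05
rs78222414	chr2	73977449	ZBTB26	-0.8	lt0.05
rs78222414	chr2	73977449	ZBTB6	-0.8	lt0.05
rs6770112	chr3	49136573	ZNF135	-0.8	lt0.05
rs6449345	chr4	17932771	FOXH1	-0.8	lt0.05
rs112525610	chr4	17953199	EOMES	-0.8	lt0.05
rs112525610	chr4	17953199	ZIC2	-0.8	lt0.05
rs62362545	chr5	103011748	HOXC10	-0.8	lt0.05
rs62362545	chr5	103011748	POU2F1	-0.8	lt0.05
rs113661575	chr5	134594467	ZNF135	-0.8	lt0.05
rs4700390	chr5	60786718	E2F1	-0.8	lt0.05
rs4700390	chr5	60786718	E2F4	-0.8	lt0.05
rs3815082	chr6	30146178	STAT5A	-0.8	lt0.05
rs3815082	chr6	30146178	STAT5B	-0.8	lt0.05
rs3815082	chr6	30146178	ZNF189	-0.8	lt0.05
rs2723264	chr12	40258718	BHLHA15	-0.8	lt0.05
rs2723264	chr12	40258718	ISL1	-0.8	lt0.05
rs2723264	chr12	40258718	NEUROD1	-0.8	lt0.05
rs2723264	chr12	40258718	NEUROG2	-0.8	lt0.05
rs2723264	chr12	40258718	MAFB	-0.8	lt0.05
rs11071650	chr15	62052408	ZBTB6	-0.8	lt0.05
rs11071650	chr15	62052408	ATF1	-0.8	lt0.05
rs11071650	chr15	62052408	ESR2	-0.8	lt0.05
rs11071650	chr15	62052408	FOS	-0.8	lt0.05
rs11071650	chr15	62052408	FOSL1	-0.8	lt0.05
rs11071650	chr15	62052408	FOSL2	-0.8	lt0.05
rs11071650	chr15	62052408	JUN	-0.8	lt0.05
rs11071650	chr15	62052408	NFE2	-0.8	lt0.05
rs11071650	chr15	62052408	NFE2L2	-0.8	lt0.05
rs11071650	chr15	62052408	RORC	-0.8	lt0.05
rs7161856	chr15	89310952	SIX2	-0.8	lt0.05
rs11646653	chr16	28910828	ARNT	-0.8	lt0.05
rs11646653	chr16	28910828	BHLHE40	-0.8	lt0.05
rs11646653	chr16	28910828	BHLHE41	-0.8	lt0.05
rs11646653	chr16	28910828	ZNF75D	-0.8	lt0.05
rs11860998	chr16	52594506	PRDM14	-0.8	lt0.05
rs55749333	chr17	7468613	RXRA	-0.8	lt0.05
rs8121449	chr20	5057712	ZNF416	-0.8	lt0.05
rs6084993	chr20	5084447	SIX2	-0.8	lt0.05
rs6084993	chr20	5084447	TEAD1	-0.8	lt0.05
rs6084993	chr20	5084447	TEAD2	-0.8	lt0.05
rs6084993	chr20	5084447	TEAD3	-0.8	lt0.05
rs6084993	chr20	5084447	TEAD4	-0.8	lt0.05
rs6084993	chr20	5084447	NR1D1	-0.8	lt0.05
rs6084993	chr20	5084447	PPARG	-0.8	lt0.05
rs6084993	chr20	5084447	ZNF135	-0.8	lt0.05
rs208376	chr20	54006278	POU2F1	-0.8	lt0.05
rs208376	chr20	54006278	POU2F2	-0.8	lt0.05
rs208376	chr20	54006278	POU2F3	-0.8	lt0.05
rs208376	chr20	54006278	POU3F1	-0.8	lt0.05
rs12755229	chr1	65348550	NFATC1	-0.8	lt0.1
rs12755229	chr1	65348550	NFATC2	-0.8	lt0.1
rs12755229	chr1	65348550	STAT3	-0.8	lt0.1
rs12755229	chr1	65348550	ZBTB26	-0.8	lt0.1
rs10929159	chr2	236024319	ESR1	-0.8	lt0.1
rs10929159	chr2	236024319	ESR2	-0.8	lt0.1
rs34378	chr5	103064805	ZFP57	-0.8	lt0.1
rs10471496	chr5	60772520	ZNF692	-0.8	lt0.1
rs7532202	chr1	0	SYNTH_TF	-0.3	lt0.05
rs34788	chr5	0	SYNTH_TF	-0.3	lt0.05
rs3104788	chr16	0	SYNTH_TF	-0.3	lt0.05
rs1076229	chr6	0	SYNTH_TF	-0.3	lt0.05
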