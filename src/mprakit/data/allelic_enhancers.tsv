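variant_id	category	gene	tag_snp	logFC	t	p	adj_p	B
rs6689005	park_intragenic	DNAJC6		0.7237	4.32	0.000319078	0.031076676	0.2096
rs2723264	park_intragenic	LRRK2		2.4527	5.1134	4.97e-05	0.007183866	0.9203
rs7532202	park_intragenic	PINK1		-0.5914	-4.54	0.000189986	0.020278954	0.707
rs34788	gwas_ld	PAM	rs10463554/rs26431	-1.8215	-5.8955	8.37e-06	0.001765235	3.6351
rs62362545	gwas_ld	PAM	rs10463554/rs26431	0.7767	4.985	6.7e-05	0.008660957	1.8011
rs113661575	gwas_ld	TXNDC15,C5orf24	rs11950533	1.3042	8.9366	1.69e-08	1.38e-05	9.7516
rs6770112	gwas_ld	IP6K2	rs12497850	-1.2506	-4.4274	0.000247688	0.025336401	0.5192
rs55749333	gwas_ld	CHRNB1	rs12600861	-1.1298	-6.1038	5.26e-06	0.001421964	4.0717
rs4700390	gwas_ld	ELOVL7	rs1867598	-1.8774	-6.0606	5.79e-06	0.001421964	4.049
rs11646653	gwas_ld	RABEP2,CD19	rs2904880	-3.0047	-10.0393	2.39e-09	3.11e-06	11.5308
rs3104788	gwas_ld	CASC16	rs3104783	-0.5753	-5.8817	8.63e-06	0.001765235	3.4501
rs11860998	gwas_ld	CASC16	rs3104783	1.3594	5.0838	5.33e-05	0.007265473	1.9448
rs112525610	gwas_ld	LCORL	rs34025766	0.8431	5.4918	2.08e-05	0.003653424	2.8718
rs6449345	gwas_ld	LCORL	rs34025766	1.3133	4.6793	0.000136951	0.016010267	1.1253
rs3739034	gwas_ld	TMEM163	rs4954162/rs57891859	-1.7047	-8.4702	4.04e-08	2.48e-05	8.7887
rs16830920	gwas_ld	TMEM163	rs4954162/rs57891859	1.8216	6.7294	1.35e-06	0.000414713	5.455
rs3815082	gwas_ld	TRIM40	rs9261484	1.0003	6.8322	1.09e-06	0.000380922	5.6154
rs1076229	gwas_ld	TRIM40	rs9261484	0.5242	5.1996	4.08e-05	0.006252808	2.1011
rs812383	park_eqtl	GIGYF2		3.2699	10.0055	2.53e-09	3.11e-06	11.1122
rs8121449	park_eqtl	TMEM230		1.7729	7.6989	1.82e-07	8.93e-05	7.415
rs6719061	park_eqtl	C2orf82		-1.1065	-7.1117	6.04e-07	0.000247042	6.2727
rs78222414	park_eqtl	VPS13C		0.895	5.5766	1.72e-05	0.00324324	3.0401
rs2746478	park_eqtl	ATP13A2		-1.5447	-5.2525	3.61e-05	0.005903798	2.269
rs7161856	park_eqtl	POLG		-0.8109	-4.7258	0.000122782	0.015071546	1.1188
rs208376	park_eqtl	DNAJC6		-0.5213	-4.566	0.000178715	0.019943008	0.7345
rs6084993	park_eqtl	TMEM230		-0.6038	-4.3069	0.000329122	0.031076676	0.2192
rs11071650	park_eqtl	VPS13C		1.0959	4.2631	0.000364996	0.033187599	0.2536
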