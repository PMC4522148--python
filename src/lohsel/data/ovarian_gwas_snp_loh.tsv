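# Genotype counts at ovarian-cancer GWAS risk SNPs in a published 364-sample
# ovarian carcinoma cohort (germline vs tumour array genotypes).
# het  = germline and tumour both heterozygous
# hom  = germline homozygous (uninformative for allele loss)
# aa   = germline heterozygous, tumour homozygous for array allele A
# bb   = germline heterozygous, tumour homozygous for array allele B
# nc   = no call in either compartment
# risk_allele: minor/major = population frequency of the risk allele;
#              /A or /B = array allele carrying the risk allele.
# lead_snp: GWAS-named SNP the row is linked to (r2 > 0.7); self when the
#           named SNP is typed directly on the array (r2 blank).
# reported_* columns are the published summary statistics for cross-checks.
snp_id	lead_snp	locus	risk_allele	het	hom	aa	bb	nc	n	reported_p	reported_direction	reported_pct_loh	reported_n_loh	array_id	r2
rs1243188	rs1243180	10p12	minor/A	112	183	22	6	41	364	0.0025	yes	0.20	28	SNP_A-2024177	0.881
rs7098100	rs1243180	10p12	minor/B	132	181	1	9	41	364	0.0114	yes	0.07	10	SNP_A-8636193	0.781
rs11658063	rs757210	17q12	minor/B	23	148	44	44	105	364	1.0000	.	0.79	88	SNP_A-8714923	0.704
rs4451990	rs9303542	17q21	minor/B	20	197	49	61	37	364	0.2526	.	0.85	110	SNP_A-2282117	1
rs12944592	rs9303542	17q21	minor/B	24	198	54	60	28	364	0.5741	.	0.83	114	SNP_A-1836563	1
rs12452212	rs9303542	17q21	minor/A	19	196	74	53	22	364	0.0624	yes	0.87	127	SNP_A-2128564	1
rs9894812	rs9303542	17q21	minor/A	20	198	70	48	28	364	0.0428	yes	0.86	118	SNP_A-2209606	1
rs34084277	rs8170	19p13	minor/B	80	260	9	8	7	364	0.8084	.	0.18	17	SNP_A-1788674	1
rs711830	rs2072590	2q31	minor/B	77	160	8	14	105	364	0.2008	.	0.22	22	SNP_A-8652216	0.965
rs344008	rs7651446	3q25	minor/A	58	297	2	3	4	364	0.6547	.	0.08	5	SNP_A-8543714	0.85
rs2292336	rs7651446	3q25	minor/B	48	299	2	5	10	364	0.2568	.	0.13	7	SNP_A-8587822	0.85
rs17380639	rs7651446	3q25	minor/A	28	320	11	3	2	364	0.0325	yes	0.33	14	SNP_A-2078455	0.85
rs11782652	rs11782652	8q21	minor/B	38	291	8	7	20	364	0.7963	.	0.28	15	SNP_A-870265
rs10088218	rs10088218	8q24	major/A	47	280	11	11	15	364	1.0000	.	0.32	22	SNP_A-180141
rs1516974	rs10088218	8q24	major/A	45	291	4	15	9	364	0.0116	no	0.30	19	SNP_A-2088878	1
rs7032221	rs3814113	9p22	major/B	123	201	6	11	23	364	0.2253	yes	0.12	17	SNP_A-8603886	1
rs10738467	rs3814113	9p22	major/B	111	206	5	11	31	364	0.1336	yes	0.13	16	SNP_A-8328297	0.892
rs10962668	rs3814113	9p22	major/B	103	177	7	22	55	364	0.0053	yes	0.22	29	SNP_A-4198891	0.794
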