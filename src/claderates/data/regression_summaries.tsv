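dataset	genome	response	predictor	coefficient	r_squared	df	p_two
mito_family	mitochondrial	clade_size	dN	-1.1185	0.1279	27	0.066
mito_family	mitochondrial	clade_size	T	-0.6133	0.0128	27	0.560
mito_family	mitochondrial	clade_size	dS	-0.0865	0.0867	16	0.236
mito_family	mitochondrial	clade_size	omega	-0.0077	0.2127	16	0.054
mito_family	mitochondrial	clade_size	body_mass	0.1398	0.0130	27	0.545
mito_family	mitochondrial	dN	body_mass	-0.0073	0.0003	27	0.921
mito_family	mitochondrial	T	body_mass	0.0017	0.0001	27	0.968
mito_family	mitochondrial	dS	body_mass	-0.2046	0.0024	16	0.846
mito_family	mitochondrial	omega	body_mass	-0.2721	0.1371	16	0.130
mito_deep	mitochondrial	clade_size	dN	-0.6282	0.0199	8	0.698
mito_deep	mitochondrial	clade_size	T	2.8130	0.1062	8	0.358
mito_deep	mitochondrial	clade_size	body_mass	-0.4004	0.0666	8	0.472
mito_deep	mitochondrial	dN	body_mass	-0.0117	0.0011	8	0.927
mito_deep	mitochondrial	T	body_mass	-0.0339	0.0351	8	0.602
mito_shallow	mitochondrial	clade_size	dN	0.2991	0.0051	25	0.722
mito_shallow	mitochondrial	clade_size	T	-0.5455	0.0069	25	0.683
mito_shallow	mitochondrial	clade_size	dS	-1.0500	0.1087	23	0.107
mito_shallow	mitochondrial	clade_size	omega	-0.0035	0.0010	23	0.88
mito_shallow	mitochondrial	clade_size	body_mass	0.1566	0.0278	24	0.416
mito_shallow	mitochondrial	dN	body_mass	0.0006	0.000006	24	0.990
mito_shallow	mitochondrial	T	body_mass	-0.0444	0.0960	24	0.123
mito_shallow	mitochondrial	dS	body_mass	0.0280	0.0074	23	0.683
mito_shallow	mitochondrial	omega	body_mass	-1.1831	0.0159	23	0.553
mito_reanalysis	mitochondrial	clade_size	dN	-0.2485	0.0064	42	0.605
mito_reanalysis	mitochondrial	clade_size	dS	-1.4968	0.1031	26	0.096
mito_reanalysis	mitochondrial	clade_size	omega	0.4371	0.0179	27	0.423
mito_reanalysis	mitochondrial	clade_size	body_mass	0.0783	0.0066	42	0.600
mito_reanalysis	mitochondrial	dN	body_mass	0.0545	0.0306	42	0.256
mito_reanalysis	mitochondrial	dS	body_mass	-0.1263	0.1728	25	0.031
mito_reanalysis	mitochondrial	omega	body_mass	0.0586	0.0338	36	0.269
nuc_mammalia	nuclear	clade_size	dN	-0.5432	0.0252	25	0.421
nuc_mammalia	nuclear	clade_size	dS	0.0987	0.0034	26	0.765
nuc_mammalia	nuclear	clade_size	omega	-1.2561	0.1022	26	0.097
nuc_mammalia	nuclear	clade_size	T	-0.4149	0.0094	23	0.645
nuc_mammalia	nuclear	clade_size	body_mass	0.0414	0.0022	31	0.793
nuc_mammalia	nuclear	dN	body_mass	-0.1062	0.1569	25	0.041
nuc_mammalia	nuclear	dS	body_mass	-0.1292	0.2794	25	0.004
nuc_mammalia	nuclear	omega	body_mass	0.0287	0.0154	26	0.529
nuc_mammalia	nuclear	T	body_mass	-0.1237	0.3384	22	0.002
nuc_eutheria	nuclear	clade_size	dN	0.8154	0.05681	18	0.312
nuc_eutheria	nuclear	clade_size	dS	1.2337	0.1111	18	0.151
nuc_eutheria	nuclear	clade_size	omega	-1.6541	0.1499	15	0.125
nuc_eutheria	nuclear	clade_size	T	1.8792	0.1839	20	0.0453
nuc_eutheria	nuclear	clade_size	body_mass	-0.1453	0.0308	22	0.4123
nuc_eutheria	nuclear	dN	body_mass	-0.2412	0.3446	18	0.0065
nuc_eutheria	nuclear	dS	body_mass	-0.1759	0.2149	18	0.0395
nuc_eutheria	nuclear	omega	body_mass	0.1272	0.1433	15	0.134
nuc_eutheria	nuclear	T	body_mass	-0.0925	0.2397	20	0.0208
nuc_metatheria	nuclear	clade_size	dN	2.2613	0.1736	6	0.304
nuc_metatheria	nuclear	clade_size	dS	-1.6842	0.2381	6	0.221
nuc_metatheria	nuclear	clade_size	omega	1.5536	0.3391	6	0.132
nuc_metatheria	nuclear	clade_size	T	-2.6421	0.1202	6	0.401
nuc_metatheria	nuclear	clade_size	body_mass	0.7831	0.3792	6	0.14
nuc_metatheria	nuclear	dN	body_mass	0.1231	0.2758	6	0.181
nuc_metatheria	nuclear	dS	body_mass	-0.0644	0.0306	6	0.679
nuc_metatheria	nuclear	omega	body_mass	0.1876	0.1549	6	0.335
nuc_metatheria	nuclear	T	body_mass	-0.0094	0.0031	6	0.895
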