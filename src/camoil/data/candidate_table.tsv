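group	gene_hg	gene_m43	ko	description	fc_hg	fc_m43	ratio
I	TRINITY_DN16539_c0_g1_i1_2	TRINITY_DN24218_c0_g1_i2_1	ko00592	alpha-Linolenic acid metabolism	3.03	8.20	2.71
I	TRINITY_DN28162_c1_g1_i1_1	TRINITY_DN30108_c1_g2_i3_1	ko00592	alpha-Linolenic acid metabolism	2.62	32.56	12.43
I	TRINITY_DN28042_c0_g1_i1_2	TRINITY_DN30108_c0_g1_i1_1	ko00592	alpha-Linolenic acid metabolism	2.30	6.97	3.03
I	TRINITY_DN20394_c0_g1_i1_2	TRINITY_DN24587_c0_g1_i1_1	ko00010/ko00040/ko00561	Glycolysis/gluconeogenesis/pentose and glucuronate interconversions/glycerolipid metabolism	4.58	9.97	2.17
I	TRINITY_DN10717_c0_g1_i1_2	TRINITY_DN25787_c1_g1_i1_1	ko00062/ko04626	Fatty acid elongation/plant-pathogen interaction	8.62	~	~
I	TRINITY_DN21443_c0_g1_i1_2	TRINITY_DN32311_c1_g3_i3_2	ko01040	Biosynthesis of unsaturated fatty acids	2.01	5.79	2.88
II	TRINITY_DN25522_c0_g1_i1_1	TRINITY_DN32370_c0_g1_i4_2	ko00592	alpha-Linolenic acid metabolism	0.15	0.33	2.21
II	TRINITY_DN16629_c0_g1_i1_1	TRINITY_DN23517_c0_g1_i1_2	ko00010/ko00071/ko00350	Glycolysis/gluconeogenesis/fatty acid degradation/tyrosine metabolism	0.06	0.20	3.31
II	TRINITY_DN27681_c1_g3_i1_1	TRINITY_DN35019_c2_g1_i6_2	ko00561/ko00564	Glycerolipid metabolism/glycerophospholipid metabolism	0.21	0.47	2.21
II	TRINITY_DN846_c0_g1_i1_1	TRINITY_DN33688_c2_g1_i1_2	ko00561	Glycerolipid metabolism	0.00	0.11	~
II	TRINITY_DN29928_c0_g2_i4_1	TRINITY_DN27234_c0_g1_i1_1	ko00061/ko00254/ko00620/ko00640	Fatty acid biosynthesis/aflatoxin biosynthesis/pyruvate metabolism/propanoate metabolism	0.05	0.35	6.50
III	TRINITY_DN30040_c0_g3_i1_1	TRINITY_DN19234_c0_g1_i1_1	ko00073	Cutin, suberine, and wax biosynthesis	0.14	15.90	115.35
III	TRINITY_DN21501_c0_g1_i1_1	TRINITY_DN26190_c1_g1_i1_1	ko00100/ko00909	Steroid biosynthesis/sesquiterpenoid and triterpenoid biosynthesis	0.31	19.86	63.23
III	TRINITY_DN24679_c0_g2_i1_1	TRINITY_DN27816_c0_g1_i1_1	ko00564	Glycerophospholipid metabolism	0.39	2.47	6.32
III	TRINITY_DN26036_c4_g4_i3_1	TRINITY_DN29951_c2_g2_i5_1	ko00564	Glycerophospholipid metabolism	0.02	14.05	732.15
III	TRINITY_DN29303_c2_g1_i4_1	TRINITY_DN24438_c0_g1_i1_1	ko00561	Glycerolipid metabolism	0.47	2.24	4.81
III	TRINITY_DN29601_c0_g3_i9_1	TRINITY_DN30355_c1_g1_i2_1	ko00561	Glycerolipid metabolism	0.39	2.44	6.21
IV	TRINITY_DN19520_c0_g1_i1_1	TRINITY_DN2720_c0_g1_i1_1	ko00591	Linoleic acid metabolism	0.37	2.45	6.62
IV	TRINITY_DN16030_c0_g1_i1_2	TRINITY_DN30055_c1_g2_i2_1	ko00592	alpha-Linolenic acid metabolism	0.33	1.03	3.07
IV	TRINITY_DN29437_c0_g1_i10_1	TRINITY_DN35593_c1_g3_i1_2	ko00592	alpha-Linolenic acid metabolism	0.24	0.65	2.74
IV	TRINITY_DN23188_c1_g1_i1_1	TRINITY_DN24343_c0_g2_i3_1	ko00071	Fatty acid degradation	0.00	0.60	~
IV	TRINITY_DN29729_c0_g2_i1_1	TRINITY_DN23466_c2_g1_i2_2	ko00061/ko00071/ko04146	Fatty acid biosynthesis/fatty acid degradation/peroxisome	0.42	1.74	4.11
IV	TRINITY_DN28894_c0_g2_i1_1	TRINITY_DN35399_c0_g3_i1_2	ko00061/ko00071/ko04146	Fatty acid biosynthesis/fatty acid degradation/peroxisome	0.25	0.52	2.08
IV	TRINITY_DN25437_c0_g1_i1_1	TRINITY_DN30757_c0_g1_i1_1	ko00600	Sphingolipid metabolism	0.24	2.57	10.67
IV	TRINITY_DN26102_c2_g4_i1_1	TRINITY_DN31693_c4_g3_i1_2	ko00511/ko00600	Other glycan degradation/sphingolipid metabolism	0.24	0.74	3.09
IV	TRINITY_DN29059_c1_g1_i4_1	TRINITY_DN27160_c0_g1_i1_1	ko00564	Glycerophospholipid metabolism	0.46	1.86	4.03
IV	TRINITY_DN23273_c1_g1_i1_1	TRINITY_DN28897_c0_g1_i4_2	ko00100	Steroid biosynthesis	0.13	1.00	7.75
IV	TRINITY_DN27207_c0_g1_i3_1	TRINITY_DN27509_c2_g1_i11_1	ko00100	Steroid biosynthesis	0.36	0.76	2.11
IV	TRINITY_DN20079_c0_g1_i2_1	TRINITY_DN20611_c0_g1_i1_1	ko00561	Glycerolipid metabolism	0.32	0.75	2.36
IV	TRINITY_DN30241_c2_g1_i9_1	TRINITY_DN27804_c1_g2_i1_1	ko00564/ko00565/ko04144	Glycerophospholipid metabolism/ether lipid metabolism/endocytosis	0.33	2.10	6.39
IV	TRINITY_DN17458_c1_g1_i1_1	TRINITY_DN30850_c1_g3_i1_2	ko00564/ko00565/ko04144	Glycerophospholipid metabolism/ether lipid metabolism/endocytosis	0.00	0.51	~
IV	TRINITY_DN26926_c1_g2_i10_1	TRINITY_DN32652_c2_g2_i6_2	ko00564/ko00565	Glycerophospholipid metabolism/ether lipid metabolism	0.25	0.57	2.23
V	TRINITY_DN11159_c0_g1_i1_2	TRINITY_DN22144_c0_g1_i1_1	ko00600	Sphingolipid metabolism	1.53	3.48	2.27
V	TRINITY_DN15140_c0_g1_i1_1	TRINITY_DN23601_c0_g1_i2_1	ko00600	Sphingolipid metabolism	0.58	7.34	12.59
V	TRINITY_DN15365_c0_g1_i1_2	TRINITY_DN32115_c0_g1_i1_1	ko00062/ko04626	Fatty acid elongation/plant-pathogen interaction	2.44	~	~
V	TRINITY_DN18887_c0_g1_i1_1	TRINITY_DN27285_c0_g1_i2_1	ko00062/ko04626	Fatty acid elongation/plant-pathogen interaction	0.75	2.92	3.90
V	TRINITY_DN19430_c0_g1_i1_1	TRINITY_DN27285_c0_g2_i2_1	ko00062/ko04626	Fatty acid elongation/plant-pathogen interaction	0.98	4.30	4.40
V	TRINITY_DN25961_c1_g2_i1_2	TRINITY_DN27285_c0_g3_i1_1	ko00062/ko04626	Fatty acid elongation/plant-pathogen interaction	1.48	115.07	77.76
V	TRINITY_DN21049_c0_g1_i1_2	TRINITY_DN24633_c0_g1_i1_1	ko00062/ko01040	Fatty acid elongation/biosynthesis of unsaturated fatty acids	0.92	3.58	3.91
V	TRINITY_DN7374_c0_g1_i1_1	TRINITY_DN6506_c0_g1_i1_1	ko00062/ko01040	Fatty acid elongation/biosynthesis of unsaturated fatty acids	1.05	3.00	2.85
V	TRINITY_DN17930_c0_g1_i1_1	TRINITY_DN21306_c0_g1_i1_1	ko00564/ko00565/ko04144	Glycerophospholipid metabolism/ether lipid metabolism/endocytosis	0.83	6.11	7.33
V	TRINITY_DN20368_c0_g1_i1_2	TRINITY_DN24269_c0_g1_i2_1	ko00564	Glycerophospholipid metabolism	1.58	3.29	2.08
V	TRINITY_DN22290_c0_g2_i1_2	TRINITY_DN26386_c2_g5_i1_1	ko00564	Glycerophospholipid metabolism	0.56	2.16	3.85
V	TRINITY_DN28036_c0_g2_i3_1	TRINITY_DN28544_c0_g1_i5_1	ko00564	Glycerophospholipid metabolism	0.76	2.10	2.77
V	TRINITY_DN18298_c0_g1_i1_1	TRINITY_DN22374_c0_g1_i1_1	ko00561/ko00564	Glycerolipid metabolism/glycerophospholipid metabolism	1.18	2.85	2.41
V	TRINITY_DN20304_c0_g1_i1_1	TRINITY_DN20388_c0_g1_i2_1	ko00561	Glycerolipid metabolism	1.78	3.65	2.05
V	TRINITY_DN23410_c0_g1_i1_1	TRINITY_DN23078_c0_g1_i2_1	ko00561	Glycerolipid metabolism	0.67	2.51	3.73
V	TRINITY_DN27117_c0_g1_i6_2	TRINITY_DN30251_c2_g1_i2_1	ko00561/ko00564/ko04070	Glycerolipid metabolism/glycerophospholipid metabolism/phosphatidylinositol signaling system	1.91	4.17	2.19
V	TRINITY_DN27969_c6_g1_i5_2	TRINITY_DN29893_c0_g3_i1_1	ko00561	Glycerolipid metabolism	0.93	2.46	2.64
V	TRINITY_DN20974_c0_g1_i1_2	TRINITY_DN20019_c0_g1_i1_1	ko00592	alpha-Linolenic acid metabolism	1.26	4.43	3.51
V	TRINITY_DN24038_c0_g1_i1_2	TRINITY_DN27084_c0_g1_i2_1	ko00592	alpha-Linolenic acid metabolism	1.39	3.20	2.31
V	TRINITY_DN25575_c0_g2_i1_1	TRINITY_DN23850_c1_g1_i1_1	ko00480/ko00590	Glutathione metabolism/arachidonic acid metabolism	0.72	7.94	11.00
V	TRINITY_DN28455_c1_g1_i7_2	TRINITY_DN30495_c3_g2_i2_1	ko00073	Cutin, suberine, and wax biosynthesis	1.13	11.66	10.36
V	TRINITY_DN27207_c0_g1_i3_1	TRINITY_DN30341_c0_g1_i3_1	ko00100/ko00909	Steroid biosynthesis/sesquiterpenoid and triterpenoid biosynthesis	2.89	50.80	17.55
V	TRINITY_DN18365_c0_g2_i1_1	TRINITY_DN30341_c0_g2_i2_1	ko00100/ko00909	Steroid biosynthesis/sesquiterpenoid and triterpenoid biosynthesis	0.61	15.65	25.68
V	TRINITY_DN26549_c2_g1_i1_1	TRINITY_DN26052_c3_g2_i1_1	ko00100	Steroid biosynthesis	1.12	11.09	9.89
V	TRINITY_DN28994_c1_g1_i1_1	TRINITY_DN30362_c1_g2_i13_1	ko00100	Steroid biosynthesis	0.64	2.03	3.17
V	TRINITY_DN4285_c0_g1_i1_2	TRINITY_DN21633_c0_g1_i1_1	ko00100	Steroid biosynthesis	1.18	29.87	25.32
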