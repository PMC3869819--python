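amplicon	gene	mutations	lines_screened	size_bp	printed_density
bn1	Stearoyl-acyl carrier protein desaturase	21	1152	1505	1/72
bn2	Acyl-ACP thioesterase A	8	1152	1534	1/192
bn3	beta-ketoacyl-ACP synthetase II	28	1920	1579	1/95
bn4	Lycopene epsilon cyclase	22	1536	1813	1/112
bn5	Acyl-ACP thioesterase B	20	1152	1655	1/84
bn6	Dihydroflavonol reductase	13	1536	1596	1/165
bn7	GLABRA 2 homologue	21	1152	1748	1/85
bn9	Phosphatidylinositol-dependent phospholipase 2	26	1536	1377	1/70
bn13	Lysophosphatidylcholine acyltransferase	11	1152	1689	1/156
bn14	Lysophosphatidylcholine acyltransferase	21	1536	2100	1/139
bn15	TRANSPARENT TESTA 16 homologue	17	1920	1605	1/159
bn17	Myo-inositol phosphate synthase	38	1536	1583	1/56
bn19	TRANSPARENT TESTA 16 homologue	12	1152	1695	1/143
bn20	DE-ETIOLATED homologue	9	1152	1702	1/192
bn21	Diglyceride acyltransferase 1	10	1536	1181	1/150
bn22	Diglyceride acyltransferase 1	2	384	1805	1/308
bn23	Diglyceride acyltransferase 1	29	1536	1798	1/85
bn25	BREVIPEDICELLUS homologue	10	1152	1306	1/127
bn26	BREVIPEDICELLUS homologue	12	1152	1739	1/148
bn27	MUCILAGE MODIFIED 4 homologue	7	1152	1761	1/257
bn29	Acyl-ACP thioesterase A	17	1152	1487	1/87
bn30	Acyl-ACP thioesterase B	14	1152	1392	1/98
bn31	beta-ketoacyl-ACP synthetase II	17	768	1457	1/57
bn36	FUSCA 3 homologue	15	1536	1781	1/162
bn37	WRINKLED 1 homologue	12	768	1782	1/101
bn39	HIGH-LEVEL EXPRESSION OF SUGAR-INDUCIBLE GENE 2 homologue	20	1536	1391	1/91
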