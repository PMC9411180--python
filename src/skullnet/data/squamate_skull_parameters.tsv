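taxon	N	K	D	C	L	H	P
Anilius	39	91	0.1228	0.4276	3.1134	0.4406	0.7811
Anomochilus	41	81	0.0988	0.3181	3.5897	0.5060	0.8209
Cylindrophis	45	96	0.0970	0.3664	3.5091	0.4645	0.7714
Rhinophis	35	72	0.1210	0.4642	3.1815	0.4633	0.7853
Uropeltis	35	68	0.1143	0.3500	3.2118	0.4906	0.7478
Casarea	49	107	0.0910	0.4522	4.0765	0.4199	0.7888
Boa	45	94	0.0949	0.3760	3.9263	0.4457	0.8148
Calabaria	47	95	0.0879	0.2770	3.7299	0.5131	0.7614
Eryx	45	95	0.0960	0.3760	3.8758	0.4311	0.8148
Acrochordus	43	77	0.0853	0.2257	4.5969	0.5214	0.8069
Aparallactus	45	83	0.0838	0.2875	4.2677	0.4999	0.7180
Atractaspis	41	67	0.0817	0.1857	4.7512	0.5212	0.7531
Lampropeltis	43	81	0.0897	0.2763	4.1030	0.5208	0.6533
Naja	43	77	0.0853	0.2123	4.3865	0.5525	0.6555
Homalopsis	43	88	0.0975	0.2768	3.8228	0.4486	0.7572
Thamnophis	43	75	0.0831	0.2275	4.2182	0.5210	0.6879
Pareas	43	79	0.0875	0.3412	4.0853	0.5168	0.7074
Crotalus	43	67	0.0742	0.1802	4.8126	0.5611	0.8643
Loxocemus	47	95	0.0879	0.2776	3.9112	0.5157	0.7614
Python	47	105	0.0971	0.4102	3.7761	0.4399	0.7777
Xenopeltis	41	79	0.0963	0.3467	4.1049	0.4085	0.7567
Anomalepis	37	59	0.0886	0.4706	3.8807	0.5621	0.8108
Helminthophis	40	65	0.0833	0.4479	4.0427	0.5861	0.8125
Liotyphlops albirostris	41	68	0.0829	0.4427	4.2186	0.5495	0.8638
Liotyphlops argaleus	41	68	0.0829	0.4427	4.2186	0.5495	0.8638
Liotyphlops beui	41	67	0.0817	0.4227	4.0472	0.5965	0.8150
Typhlophis	40	62	0.0795	0.4211	4.2774	0.5308	0.8638
Epictia	40	97	0.1244	0.4735	3.4397	0.4418	0.7725
Myriopholis macrorhyncha	41	95	0.1159	0.4773	3.5085	0.4647	0.8245
Myriopholis tanae	40	85	0.1090	0.4588	3.8667	0.4758	0.8250
Rena	39	95	0.1282	0.4769	3.4345	0.4447	0.7705
Tricheilostoma	36	78	0.1238	0.4790	3.5746	0.4903	0.7870
Trilepida	39	93	0.1255	0.4634	3.4507	0.4421	0.7771
Gerrhopilus ater	35	66	0.1109	0.4776	3.8958	0.4020	0.7739
Gerrhopilus beddomii	31	58	0.1247	0.5048	3.5548	0.4138	0.8429
Acutotyphlops solomonis	36	72	0.1143	0.5196	4.0127	0.3732	0.7377
Acutotyphlops subocularis	36	74	0.1175	0.5272	3.7841	0.4061	0.7824
Afrotyphlops	40	89	0.1141	0.5116	3.8705	0.3840	0.6825
Amerotyphlops	40	87	0.1115	0.4994	3.9167	0.3513	0.6825
Anilios	38	83	0.1181	0.4940	3.6046	0.4033	0.7355
Antillotyphlops	40	85	0.1090	0.4941	3.9192	0.3796	0.6825
Indotyphlops	35	66	0.1109	0.4554	3.8958	0.4270	0.7739
Ramphotyphlops	33	63	0.1193	0.4968	3.9356	0.3787	0.7787
Typhlops	40	89	0.1141	0.5116	3.8705	0.3840	0.6825
Xerotyphlops	38	81	0.1152	0.4901	3.8094	0.3726	0.7604
Xenotyphlops	37	80	0.1201	0.5171	3.4730	0.5314	0.8006
Amphisbaena	37	83	0.1246	0.5353	3.1351	0.4288	0.7232
Bipes	30	67	0.1540	0.5963	2.8759	0.5380	0.6200
Rhineura	36	94	0.1492	0.5658	2.8540	0.4693	0.7701
Anelytropsis	47	107	0.0990	0.5212	3.3673	0.4435	0.7759
Dibamus	37	90	0.1351	0.5293	3.2583	0.3292	0.7363
Physignathus	54	135	0.0943	0.4717	3.3487	0.3561	0.8203
Dipsosaurus	52	126	0.0950	0.4861	3.3718	0.3798	0.7633
Sauromalus	50	118	0.0963	0.4536	3.4188	0.3924	0.7608
Uranoscodon	56	134	0.0870	0.4492	3.4825	0.3774	0.8182
Lanthanotus	54	135	0.0943	0.4966	3.5618	0.3624	0.8354
Varanus	57	130	0.0815	0.4669	3.9467	0.3636	0.7584
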