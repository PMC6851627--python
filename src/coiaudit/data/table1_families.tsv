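infraorder	family	species_reported	n_clusters	ratio_barcoded	size_lo	size_hi	taxa_with_barcode	unnamed_with_barcode	pct_dark
Brachycera	Acartophthalmidae	2	1	50	1.0	2.5	2	0	0
Brachycera	Acroceridae	11	0	0	2.5	20.0	NA	NA	NA
Brachycera	Agromyzidae	552	218	39	1.0	6.0	214	149	70
Nematocera	Anisopodidae (& Mycetobiidae)	8	7	88	4.0	12.0	7	2	29
Brachycera	Anthomyiidae	227	188	83	4.0	12.0	178	64	36
Brachycera	Anthomyzidae	14	5	36	1.3	4.5	5	0	0
Brachycera	Asilidae	81	18	22	8.0	20.0	18	6	33
Brachycera	Asteiidae	7	3	43	1.0	3.0	3	0	0
Brachycera	Atelestidae	3	3	100	1.5	3.5	3	0	0
Brachycera	Athericidae	5	3	60	7.5	10.0	3	1	33
Brachycera	Aulacigastridae	1	0	0	2.0	5.0	0	0	NA
Nematocera	Bibionidae (& Pleciidae)	21	12	57	2.0	15.0	10	2	20
Nematocera	Blephariceridae	7	2	29	3.0	15.0	2	1	50
Nematocera	Bolitophilidae	22	14	64	4.0	7.0	13	7	54
Brachycera	Bombyliidae	40	6	15	1.0	20.0	6	1	17
Brachycera	Braulidae	1	0	0	1.2	2.5	2	0	0
Brachycera	Calliphoridae	62	35	56	4.0	16.0	39	6	15
Brachycera	Camillidae	4	0	0	2.0	3.5	NA	NA	NA
Brachycera	Campichoetidae	3	0	0	2.5	4.0	NA	NA	NA
Brachycera	Canacidae	2	9	450	1.6	5.0	9	1	11
Nematocera	Canthyloscelidae	1	0	0	2.5	9.0	NA	NA	NA
Brachycera	Carnidae	11	7	64	1.0	2.5	7	7	100
Nematocera	Cecidomyiidae	836	927	111	0.5	3.0	926	882	95
Nematocera	Ceratopogonidae	332	131	39	1.0	5.0	128	97	76
Brachycera	Chamaemyiidae	29	17	59	1.0	5.0	17	13	76
Nematocera	Chaoboridae	7	2	29	2.0	10.0	2	0	0
Nematocera	Chironomidae	696	455	65	1.0	10.0	438	286	65
Brachycera	Chloropidae	198	101	51	1.0	5.0	101	59	58
Brachycera	Chyromyidae	5	2	40	0.5	8.0	2	0	0
Brachycera	Clusiidae	9	6	67	1.5	8.0	7	3	43
Brachycera	Coelopidae	2	0	0	2.5	9.0	NA	NA	NA
Brachycera	Coenomyiidae	1	0	0	14.0	20.0	NA	NA	NA
Brachycera	Conopidae	52	9	17	5.0	15.0	9	0	0
Brachycera	Cremifaniidae	1	0	0	1.5	2.6	NA	NA	NA
Brachycera	Cryptochetidae	1	0	0	2.0	4.0	NA	NA	NA
Nematocera	Culicidae	46	8	17	3.0	9.0	7	0	0
Nematocera	Cylindrotomidae	4	1	25	11.0	16.0	1	0	0
Nematocera	Diadocidiidae	4	3	75	3.0	4.5	3	0	0
Brachycera	Diastatidae	6	8	133	2.5	4.0	8	2	25
Nematocera	Ditomyiidae	4	1	25	6.0	8.0	1	0	0
Nematocera	Dixidae	16	4	25	3.0	5.5	4	1	25
Brachycera	Dolichopodidae	356	112	31	1.0	9.0	112	58	52
Brachycera	Drosophilidae	59	28	47	1.5	7.0	28	5	18
Brachycera	Dryomyzidae	3	2	67	5.0	18.0	2	1	50
Brachycera	Eginiidae	1	0	0	2.0	18.0	NA	NA	NA
Brachycera	Empididae (& Brachystomatidae)	383	161	42	1.0	12.0	161	107	66
Brachycera	Ephydridae	177	130	73	1.0	11.0	132	16	12
Brachycera	Fanniidae	56	46	82	2.0	5.0	44	13	30
Brachycera	Gasterophilidae	4	0	0	9.0	16.0	NA	NA	NA
Brachycera	Helcomyzidae	3	0	0	6.0	11.0	NA	NA	NA
Brachycera	Heleomyzidae (& Heteromyzidae)	74	58	78	1.2	12.0	55	26	47
Nematocera	Hesperinidae	1	0	0	4.0	6.0	NA	NA	NA
Brachycera	Hilarimorphidae	2	0	0	2.0	7.0	NA	NA	NA
Brachycera	Hippoboscidae	12	7	58	2.5	10.0	7	1	14
Brachycera	Hybotidae	229	140	61	1.0	6.0	139	83	60
Brachycera	Hypodermatidae	5	0	0	10.0	22.0	NA	NA	NA
Nematocera	Keroplatidae	60	30	50	4.0	15.0	30	12	40
Brachycera	Lauxaniidae	67	25	37	2.0	7.0	25	11	44
Nematocera	Limoniidae	280	96	34	2.0	11.0	91	50	55
Brachycera	Lonchaeidae	47	16	34	3.0	6.0	16	9	56
Brachycera	Lonchopteridae	9	5	56	2.0	5.0	6	0	0
Brachycera	Megamerinidae	1	1	100	6.0	9.0	1	0	0
Brachycera	Micropezidae	13	5	38	3.0	16.0	4	1	25
Brachycera	Microphoridae	6	0	0	1.5	3.0	NA	NA	NA
Brachycera	Milichiidae	13	17	131	1.0	6.0	16	9	56
Brachycera	Muscidae	317	174	55	2.0	18.0	167	66	40
Nematocera	Mycetophilidae	573	306	53	2.0	15.0	301	89	30
Brachycera	Neottiophilidae	1	0	0	1.5	7.0	NA	NA	NA
Brachycera	Nycteribiidae	8	0	0	1.5	5.0	NA	NA	NA
Brachycera	Odiniidae	9	0	0	2.0	5.0	NA	NA	NA
Brachycera	Oestridae	6	0	0	9.0	18.0	NA	NA	NA
Brachycera	Opetiidae	1	1	100	2.0	5.0	1	0	0
Brachycera	Opomyzidae	15	4	27	2.0	5.0	4	1	25
Brachycera	Otitidae	26	0	0	2.5	11.0	NA	NA	NA
Brachycera	Pallopteridae	16	8	50	2.5	7.0	7	0	0
Nematocera	Pediciidae	36	13	36	5.0	35.0	13	3	23
Brachycera	Periscelididae	6	1	17	1.0	5.0	1	0	0
Brachycera	Phaeomyiidae	3	2	67	3.0	11.0	2	0	0
Brachycera	Phoridae	364	289	79	0.5	6.0	276	166	60
Brachycera	Piophilidae	12	12	100	1.5	7.0	12	4	33
Brachycera	Pipunculidae	111	42	38	2.0	12.0	40	7	18
Brachycera	Platypezidae	23	4	17	1.5	6.0	4	0	0
Brachycera	Platystomatidae	3	2	67	3.0	11.0	2	0	0
Brachycera	Pseudopomyzidae	1	1	100	1.7	2.5	1	0	0
Brachycera	Psilidae	30	12	40	2.5	10.0	12	8	67
Nematocera	Psychodidae	143	51	36	2.0	6.0	50	25	50
Nematocera	Ptychopteridae	8	0	0	7.0	15.0	NA	NA	NA
Brachycera	Pyrgotidae	1	0	0	8.0	9.0	NA	NA	NA
Brachycera	Rhagionidae	35	20	57	2.0	20.0	20	10	50
Brachycera	Rhinophoridae	10	9	90	2.0	11.0	7	1	14
Brachycera	Sarcophagidae	130	49	38	3.0	22.0	49	17	35
Brachycera	Scatophagidae	57	0	0	3.0	12.0	0	0	NA
Nematocera	Scatopsidae	47	30	64	0.5	4.0	30	24	80
Brachycera	Scenopinidae	3	0	0	2.0	7.0	NA	NA	NA
Nematocera	Sciaridae	342	310	91	1.0	6.0	284	81	29
Brachycera	Sciomyzidae	78	19	24	2.0	14.0	18	4	22
Brachycera	Sepsidae	31	15	48	2.0	6.0	13	1	8
Nematocera	Simuliidae	50	19	38	1.2	6.0	18	9	50
Brachycera	Sphaeroceridae	137	79	58	0.7	5.5	77	31	40
Brachycera	Stratiomyidae	66	21	32	2.0	25.0	22	6	27
Brachycera	Strongylophthalmyiidae	1	0	0	3.0	5.5	NA	NA	NA
Brachycera	Syrphidae	440	242	55	3.5	35.0	297	24	8
Brachycera	Tabanidae	58	46	79	6.0	30.0	45	3	7
Brachycera	Tachinidae	494	214	43	2.0	20.0	211	76	36
Brachycera	Tanypezidae	1	1	100	5.0	8.0	1	0	0
Brachycera	Tephritidae	110	28	25	2.5	10.0	27	5	19
Brachycera	Tethinidae	10	0	0	1.5	3.5	NA	NA	NA
Nematocera	Thaumaleidae	15	13	87	3.0	5.0	13	1	8
Brachycera	Therevidae	32	4	13	2.5	15.0	4	1	25
Brachycera	Thyreophoridae	2	0	0	1.5	7.0	NA	NA	NA
Nematocera	Tipulidae	123	46	37	7.0	35.0	46	15	33
Nematocera	Trichoceridae	18	24	133	3.0	9.0	24	17	71
Brachycera	Trixoscelididae	4	0	0	2.0	4.0	NA	NA	NA
Brachycera	Ulidiidae	4	9	225	2.5	11.0	9	4	44
Brachycera	Xylomyidae	3	1	33	6.0	20.0	1	0	0
Brachycera	Xylophagidae	4	1	25	5.0	11.0	1	0	0
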