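population	distance_km	rs2263664	rs2253698	rs2746603	rs6074896	rs2209313	rs1535882	rs11696842	rs6105421	rs4814391
San	0	0,75	0,75	1,00	0,83	1,00	0,83	0,83	1,00	1,00
Mbuti	2716	0,97	0,80	1,00	0,87	1,00	0,83	0,83	0,97	1,00
Bantu speakers	2920	0,93	0,73	1,00	0,65	0,95	0,83	0,95	0,93	0,87
Biaka	2934	0,92	0,87	1,00	0,79	1,00	1,00	1,00	0,97	1,00
Yoruba	3900	0,94	0,58	1,00	0,67	0,94	0,90	0,92	0,94	0,98
Mandenka	5574	0,90	0,83	1,00	0,50	0,89	0,85	0,88	0,85	1,00
Bedouin	6400	0,94	0,47	0,99	0,66	0,90	0,67	0,89	0,98	0,78
Mozabite	6470	0,88	0,67	0,91	0,63	0,92	0,68	0,92	0,97	0,90
Palestinian	6482	0,92	0,58	0,98	0,68	0,95	0,78	0,95	0,97	0,84
Druze	6696	0,89	0,79	0,99	0,68	0,72	0,68	0,72	0,98	0,96
Adygei	7840	0,82	0,65	0,97	0,62	0,88	0,82	0,88	1,00	0,94
Italians	8708	0,88	0,67	1,00	0,72	0,88	0,71	0,88	1,00	0,81
Sardinian	8886	0,91	0,55	0,96	0,80	0,74	0,59	0,75	1,00	0,84
Balochi	9099	0,89	0,58	0,97	0,70	0,85	0,74	0,85	1,00	0,89
Brahui	9285	0,86	0,52	0,98	0,52	0,88	0,86	0,88	0,98	0,98
French	9411	0,79	0,64	0,97	0,79	0,72	0,53	0,72	1,00	0,81
Sindhi	9783	0,84	0,58	0,93	0,72	0,80	0,68	0,80	1,00	0,88
Basque	9878	0,77	0,54	0,85	0,71	0,75	0,58	0,75	1,00	0,83
Kalash	9967	0,90	0,90	1,00	0,88	0,86	0,84	0,86	1,00	0,98
Orcadian	10513	0,66	0,66	0,97	0,78	0,63	0,44	0,63	1,00	0,81
Uyghur	10945	0,85	0,85	1,00	0,80	0,90	0,90	0,90	1,00	1,00
Tu	12147	0,70	1,00	1,00	1,00	0,75	0,75	0,75	1,00	1,00
Russians	12164	0,76	0,54	0,88	0,62	0,70	0,60	0,70	1,00	0,90
Mongolian	12551	0,55	1,00	1,00	1,00	0,56	0,60	0,60	1,00	1,00
Dai	12873	0,70	0,95	1,00	1,00	0,72	0,75	0,75	1,00	1,00
Lahu	12895	0,65	0,95	1,00	0,95	0,65	0,65	0,65	1,00	1,00
Yi	13022	0,70	0,95	1,00	0,90	0,65	0,65	0,65	1,00	1,00
Miao	13126	0,70	1,00	1,00	1,00	0,70	0,70	0,70	1,00	1,00
Daur	13380	0,78	0,89	0,89	0,89	0,72	0,72	0,72	1,00	1,00
Han	13400	0,89	1,00	1,00	1,00	0,89	0,89	0,89	1,00	1,00
Tujia	13654	0,85	1,00	1,00	1,00	0,85	0,85	0,85	1,00	1,00
Cambodians, Khmer	13803	0,91	0,95	1,00	0,91	0,77	0,77	0,77	1,00	1,00
Oroqen	13803	0,65	0,95	1,00	0,95	0,70	0,70	0,70	1,00	1,00
Hezhe	14141	0,67	1,00	1,00	1,00	0,81	0,83	0,83	1,00	1,00
Naxi	14147	0,83	0,89	1,00	0,89	0,83	0,83	0,83	1,00	1,00
She	14203	0,85	0,90	1,00	0,90	0,85	0,85	0,85	1,00	1,00
Japanese	15379	0,77	1,00	1,00	0,98	0,79	0,79	0,79	1,00	1,00
Papuan New Guinean	18323	1,00	0,79	1,00	1,00	1,00	0,82	1,00	1,00	1,00
Melanesian, Nasioi	19515	0,92	0,84	1,00	1,00	0,95	0,84	0,95	1,00	1,00
Pima, Mexico	21788	0,44	0,98	1,00	0,98	0,46	0,46	0,46	1,00	1,00
Maya, Yucatan	23603	0,48	0,90	0,98	0,94	0,52	0,50	0,52	1,00	0,98
Karitiana	28012	0,35	1,00	1,00	1,00	0,42	0,42	0,42	1,00	1,00
Surui	28336	0,33	1,00	1,00	1,00	0,38	0,38	0,38	1,00	1,00
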