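family	genome_percent	divergence_k2p	rul_bp	at_percent
CameSat001-141	8.9588	7.68	141	61.0
CameSat002-187	2.4143	7.18	187	58.8
CameSat003-10	1.2658	9.60	10	40.0
CameSat004-322	0.6512	17.83	322	67.4
CameSat005-499	0.3837	11.62	499	57.5
CameSat006-2670	0.2748	2.59	2670	56.1
CameSat007-313	0.2600	11.97	313	62.6
CameSat008-454	0.2310	8.36	454	60.4
CameSat009-206	0.1666	3.63	206	61.2
CameSat010-3664	0.1401	3.63	3664	65.9
CameSat011-2186	0.1381	8.18	2186	66.3
CameSat012-346	0.1372	10.03	346	54.0
CameSat013-1223	0.1284	11.99	1223	63.2
CameSat014-163	0.1227	16.32	163	58.3
CameSat015-288	0.1225	14.10	288	58.8
CameSat016-449	0.1132	6.45	449	57.5
CameSat017-479	0.1115	9.50	479	60.1
CameSat018-280	0.0978	10.52	280	67.1
CameSat019-228	0.0967	19.91	228	66.2
CameSat020-336	0.0665	6.27	336	59.2
CameSat021-312	0.0663	13.13	312	62.5
CameSat022-324	0.0612	17.54	324	66.7
CameSat023-146	0.0571	7.12	146	63.0
CameSat024-316	0.0544	4.70	316	54.4
CameSat025-150	0.0517	3.75	150	64.7
CameSat026-65	0.0514	6.85	65	80.0
CameSat027-469	0.0496	5.69	469	62.3
CameSat028-154	0.0493	7.78	154	66.2
CameSat029-325	0.0461	10.47	325	68.1
CameSat030-132	0.0452	7.28	132	63.6
CameSat031-281	0.0440	26.18	281	66.9
CameSat032-166	0.0434	16.03	166	35.5
CameSat033-351	0.0429	16.55	351	60.4
CameSat034-191	0.0416	4.64	191	60.7
CameSat035-5-tel	0.0414	0.83	5	40.0
CameSat036-144	0.0409	4.64	144	66.0
CameSat037-1278	0.0405	2.77	1278	64.1
CameSat038-50	0.0404	13.65	50	66.0
CameSat039-400	0.0389	2.39	400	66.4
CameSat040-67	0.0377	13.60	67	64.2
CameSat041-142	0.0353	4.81	142	62.7
CameSat042-250	0.0342	18.25	250	66.8
CameSat043-151	0.0333	5.93	151	65.6
CameSat044-2844	0.0322	11.06	2844	73.6
CameSat045-143	0.0319	9.01	143	61.5
CameSat046-23	0.0301	6.47	23	56.5
CameSat047-389	0.0298	13.10	389	64.0
CameSat048-293	0.0286	17.01	293	58.4
CameSat049-20	0.0265	13.40	20	60.0
CameSat050-140	0.0258	9.00	140	67.9
CameSat051-3051	0.0255	8.78	3051	67.5
CameSat052-143	0.0238	6.67	143	66.4
CameSat053-153	0.0235	9.79	153	68.6
CameSat054-164	0.0211	8.20	164	67.1
CameSat055-30	0.0201	13.58	30	63.3
CameSat056-42	0.0198	19.82	42	69.0
CameSat057-147	0.0195	9.61	147	61.9
CameSat058-280	0.0189	6.36	280	57.1
CameSat059-128	0.0188	19.29	128	68.8
CameSat060-141	0.0188	14.68	141	59.6
CameSat061-230	0.0184	7.56	230	68.3
CameSat062-142	0.0183	12.19	142	60.6
CameSat063-2048	0.0182	5.04	2048	64.7
CameSat064-104	0.0182	2.78	104	51.0
CameSat065-148	0.0175	15.05	148	67.6
CameSat066-149	0.0175	6.94	149	66.4
CameSat067-168	0.0155	23.71	168	69.0
CameSat068-153	0.0147	8.35	153	58.8
CameSat069-142	0.0144	13.63	142	55.6
CameSat070-13	0.0142	14.35	13	53.8
CameSat071-20	0.0137	17.80	20	70.0
CameSat072-193	0.0132	8.71	193	65.3
CameSat073-20	0.0130	22.31	20	45.0
CameSat074-1625	0.0116	1.77	1625	63.1
CameSat075-275	0.0116	7.13	275	62.9
CameSat076-243	0.0114	12.69	243	61.3
CameSat077-1817	0.0103	1.95	1817	63.1
CameSat078-138	0.0102	14.13	138	67.4
CameSat079-143	0.0102	6.60	143	69.2
CameSat080-162	0.0098	16.90	162	67.9
CameSat081-125	0.0093	16.48	125	58.4
CameSat082-204	0.0091	4.98	204	57.8
CameSat083-100	0.0091	15.98	100	56.4
CameSat084-141	0.0088	11.67	141	67.4
CameSat085-625	0.0087	2.28	625	61.3
CameSat086-159	0.0087	12.12	159	66.0
CameSat087-171	0.0085	9.58	171	66.7
CameSat088-132	0.0081	12.79	132	56.1
CameSat089-151	0.0080	14.26	151	68.9
CameSat090-288	0.0079	6.61	288	63.2
CameSat091-143	0.0079	9.77	143	44.1
CameSat092-160	0.0078	13.12	160	68.8
CameSat093-182	0.0073	16.57	182	63.7
CameSat094-142	0.0071	7.69	142	62.7
CameSat095-231	0.0067	13.07	231	61.5
CameSat096-135	0.0066	17.45	135	63.0
CameSat097-76	0.0066	11.95	76	51.9
CameSat098-1148	0.0065	2.57	1148	61.1
CameSat099-146	0.0062	10.12	146	61.0
CameSat100-146	0.0062	10.34	146	71.2
CameSat101-649	0.0061	2.99	649	62.4
CameSat102-141	0.0059	11.29	141	66.0
CameSat103-172	0.0059	14.49	172	63.4
CameSat104-165	0.0058	16.43	165	64.8
CameSat105-952	0.0055	2.13	952	63.8
CameSat106-309	0.0055	7.04	309	58.3
CameSat107-212	0.0053	4.39	212	64.6
CameSat108-410	0.0052	18.03	410	65.4
CameSat109-148	0.0052	11.11	148	65.5
CameSat110-145	0.0052	13.30	145	71.0
CameSat111-160	0.0049	10.38	160	64.4
CameSat112-147	0.0049	2.93	147	63.9
CameSat113-76	0.0048	11.48	76	69.7
CameSat114-144	0.0045	15.56	144	62.5
CameSat115-14	0.0045	6.70	14	50.0
CameSat116-29	0.0044	8.17	29	51.7
CameSat117-149	0.0044	8.64	149	67.1
CameSat118-144	0.0042	7.07	144	66.0
CameSat119-140	0.0040	7.42	140	60.7
CameSat120-286	0.0040	5.94	286	60.1
CameSat121-162	0.0039	18.95	162	71.0
CameSat122-132	0.0038	14.77	132	58.3
CameSat123-161	0.0038	14.31	161	65.8
CameSat124-120	0.0037	15.51	120	59.2
CameSat125-309	0.0036	15.66	309	64.4
CameSat126-509	0.0036	17.22	509	69.7
CameSat127-410	0.0034	10.08	410	66.1
CameSat128-148	0.0034	6.09	148	57.4
CameSat129-91	0.0034	19.47	91	62.6
CameSat130-147	0.0033	11.08	147	61.2
CameSat131-149	0.0033	12.11	149	70.5
CameSat132-429	0.0030	3.43	429	63.4
CameSat133-142	0.0028	6.41	142	62.7
CameSat134-166	0.0028	5.63	166	69.3
CameSat135-148	0.0027	7.01	148	66.2
CameSat136-255	0.0027	12.48	255	65.9
CameSat137-360	0.0025	3.35	360	59.4
CameSat138-156	0.0025	7.18	156	57.7
CameSat139-369	0.0025	13.38	369	65.0
CameSat140-84	0.0025	10.28	84	57.1
CameSat141-163	0.0019	13.47	163	65.0
CameSat142-408	0.0017	10.77	408	67.9
CameSat143-184	0.0016	8.55	184	65.8
CameSat144-265	0.0015	13.25	265	63.8
CameSat145-168	0.0015	7.16	168	64.3
CameSat146-139	0.0015	8.36	139	74.1
CameSat147-154	0.0014	13.08	154	73.4
CameSat148-468	0.0014	4.06	468	59.2
CameSat149-141	0.0014	10.48	141	51.8
CameSat150-147	0.0013	4.43	147	70.1
CameSat151-300	0.0013	7.26	300	63.0
CameSat152-228	0.0012	5.41	228	59.6
CameSat153-498	0.0012	4.75	498	60.8
CameSat154-59	0.0012	9.39	59	72.9
CameSat155-496	0.0011	2.09	496	66.7
CameSat156-216	0.0011	2.84	216	60.2
CameSat157-476	0.0011	2.76	476	62.8
CameSat158-143	0.0011	9.02	143	65.0
CameSat159-272	0.0010	2.51	272	63.6
CameSat160-36	0.0009	12.37	36	63.9
CameSat161-127	0.0009	2.42	127	65.4
CameSat162-133	0.0008	4.60	133	70.7
CameSat163-416	0.0008	3.37	416	60.6
CameSat164-112	0.0006	8.95	112	67.9
CameSat165-105	0.0002	8.18	105	60.0
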