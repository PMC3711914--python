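locality_code	locality_name	lat	lon	clade_id	region
1	Vieille-Roche (France)	47.50	-2.38	1	northern
2	Palacios de Compludo (Spain)	42.46	-6.47		southern
3	Braña de Sosas (Spain)	43.00	-6.31	2	southern
4	Señora de Carrasconte (Spain)	42.94	-6.23	2	southern
5	La Omañuela (Spain)	42.78	-5.98	2	southern
6	León (Spain)	42.59	-5.58	2	southern
7	La Candamia (Spain)	42.60	-5.55	2	southern
8	Valdehuesa (Spain)	42.94	-5.32	2	southern
9	Tanes (Spain)	43.21	-5.40	2	southern
10	Turieno (Spain)	43.16	-4.66		southern
11	Matienzo (Spain)	43.33	-3.59	2	southern
12	Oriñon (Spain)	43.40	-3.33	2	southern
13	Guadarrama (Spain)	40.71	-4.14	3	southern
14	Gúdar (Spain)	40.37	-0.67	3	southern
15	Penyagolosa (Spain)	40.23	-0.35	3	southern
16	Montseny (Spain)	41.77	2.44	1	southern
17	Les Salines (Spain)	42.42	2.75		unassigned
18	Meranges (Spain)	42.43	1.78	1	southern
19	Luzenac (France)	42.75	1.75		unassigned
20	Massif des Maures (France)	43.24	6.38	6	northern
21	Valle de Gilly (France)	43.28	6.46	6	northern
22	Massif des Maures (France)	43.38	6.62	6	northern
23	Viozene (Italy)	44.14	7.78	5	northern
24	Monte Verita (Switzerland)	46.16	8.72		unassigned
25	Bianzano (Italy)	45.77	9.92	5	northern
26	Peschiera del Garda (Italy)	45.44	10.67	5	northern
27	Ostia Antica (Italy)	41.75	12.31	9	southern
28	Paganico (Italy)	42.19	13.00	9	southern
29	Majelletta (Italy)	42.16	14.13	10	southern
30	Bassiano (Italy)	41.55	13.05	9	southern
31	Fondi (Italy)	41.37	13.33	9	southern
32	Pollino National Park (Italy)	39.93	16.17	7	southern
33	Pollino National Park (Italy)	39.90	16.19	7	southern
34	Fago del Soldato (Italy)	39.35	16.55	8	southern
35	Ribnica (Slovenia)	45.75	14.77	11	northern
36	Donja Lamana Draga (Slovenia)	45.51	14.96	11	northern
37	Zuce (Serbia)	44.68	20.55	4	northern
38	Cиheвo (Serbia)	43.34	22.08	4	northern
39	Road to Crnovska River (Serbia)	42.38	22.05	4	northern
40	Metsovo (Greeece)	39.71	21.19	13	southern
41	Metsovo (Greeece)	39.71	21.21	13	southern
42	Velouxi (Greece)	38.85	21.38	14	southern
43	Platanitsa, Achaia (Greece)	37.97	21.88	14	southern
44	Platanitsa, Achaia (Greece)	37.96	21.91	14	southern
45	Mainalo, Pelloponnisos (Greece)	37.39	22.46	14	southern
46	Kisavos mt (Greece)	39.63	22.64	12	southern
47	Samothraki isl. (Greece)	40.45	25.59	16	unassigned
48	Kapakli (Turkey)	41.89	27.35	15	unassigned
49	Kapakli (Turkey)	41.91	27.36	15	unassigned
50	Dereköy (Turkey)	41.96	27.39	15	unassigned
51	Dereköy (Turkey)	41.97	27.42	15	unassigned
52	Dereköy (Turkey)	41.96	27.45	15	unassigned
53	Pınarözü (Turkey)	41.77	34.04	17	unassigned
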