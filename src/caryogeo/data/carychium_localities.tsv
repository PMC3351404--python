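code	name	lat	lon	N_CM	H_CM	pi_CM	haplotypes_CM	N_CT	H_CT	pi_CT	haplotypes_CT	transatlantic
AR	France, Argentière	45.9723	6.9173					10	0.2000	0.0010	H25,H33	no
AS	Belgium, Assenois	49.7965	5.4557					3	0	0	H1	no
AU	Italy, Auer	46.3385	11.3503	9	0	0	H20	7	0.6667	0.0032	H3,H26,H29	no
AZ1	Portugal, Azores	37.852	-25.265	4	0	0	H30	2	0	0	H2	yes
AZ2	Portugal, Azores	37.8	-25.2					8	0	0	H2	yes
BA	Germany, Baunatal	51.2574	9.3581	7	0.7619	0.0016	H1,H8,H13	13	0.6795	0.0033	H1,H7,H8,H25,H27	no
BB	Germany, Bad Herrenalb	48.8247	8.4622					6	0	0	H1	no
BE	France, Beg En Fry	48.70	-3.72					6	0	0	H1	no
BH	Germany, Bad Homburg	50.227	8.635	6	0.6000	0.0102	H1,H33					no
BI	Austria, Bichlbach	47.417	10.842					9	0	0	H1	no
BN	France, Bonnac	43.164	1.5959					12	0.1667	0.0006	H1,H16	no
BO	Czech Republic, Bohemia	50.7911	15.2103	9	0	0	H1	8	0	0	H25	no
BR	Germany, Bremen	53.09	8.82	9	0.4167	0.0008	H3,H4,H5	3	0	0	H1	no
BT	Hungary, Budapest	47.5115	19.2435	8	0.4286	0.0007	H1,H3	4	0	0	H1	no
BU	Romania, Baru	45.5119	23.2142					5	0.4000	0.0007	H22,H23	no
BY	Czech Republic, Brezany	48.8736	16.3308	1	n/a	n/a	H3					no
CE	Czech Republic, Cereniste	50.5944	14.1089					3	0	0	H25	no
CN	Romania, Cluj-Napoca	46.7613	23.5869					15	0.6762	0.0041	H21,H23,H24	no
CS	France, Ceyras	43.6453	3.4597	10	0	0	H33					no
DA	Germany, Darmstadt	49.8704	8.6783	5	0	0	H1	8	0.5714	0.0049	H1,H25	no
DI	Germany, Diessen	47.94	11.11	9	0.2222	0.0004	H30,H32					no
EC	Czech Republic, Echemia	50.8006	15.3581					4	0.5000	0.0042	H1,H25	no
EP	Italy, Eppan	46.4889	11.2464	9	0	0	H9	5	0.6000	0.0021	H19,H26	no
ER	Germany, Erdbach	50.6813	8.2168	10	0.7111	0.0069	H1,H2,H33	5	0	0	H1	no
ES	Germany, Eppstein	50.1536	8.3962					10	0.3556	0.0006	H1,H11	no
EU	Belgium, Eupen	50.59	5.98					4	0	0	H1	no
FR1	Germany, Frankfurt am Main	50.1293	8.6583	4	0.8333	0.0020	H1,H7,H11	3	0.6667	0.0068	H1,H33	no
FR2	Germany, Frankfurt am Main	50.1244	8.6542					2	0	0	H33	no
FV	Belgium, Fays Les Veneurs	49.8654	5.1615	5	0.6000	0.0010	H1,H14	2	0	0	H1	no
GA	Slovenia, Gradicek	45.8897	14.7756	4	0.5000	0.0009	H17,H18	2	0	0	H38	no
GG	Slovenia, Gornji Ig	45.9189	14.4934					10	0	0	H20	no
GH	Romania, Gheorgheni	46.7096	25.5978	5	0	0	H1	2	0	0	H23	no
GI	Spain, Gijón	43.5204	-5.6164	15	0	0	H21	1	n/a	n/a	H1	no
GM	France, Gambsheim	48.6821	7.9032					6	0	0	H1	no
GN	Germany, Gaienhofen	47.68	8.99					5	0.4000	0.0007	H1,H15	no
GR	France, Grimbosq	49.05	-0.44					3	0	0	H1	no
HA	France, Haguenau	48.8806	7.7068					10	0	0	H1	no
HU	Denmark, Humlebaek	55.9701	12.5426	3	0	0	H1	13	0.5128	0.0009	H1,H10	no
HW	United Kingdom, Hartley Wintney	51.31	-0.89	10	0	0	H1					no
IT1	USA, Ithaca	42.4008	-76.5047	9	0	0	H34					yes
IT2	USA, Ithaca	42.4494	-76.4758	10	0	0	H34					yes
KE	Germany, Kelkheim/Eppenhain	50.17	8.39	1	n/a	n/a	H33	1	n/a	n/a	H1	no
LA	Spain, La Creueta	41.9683	2.8572					3	0.6667	0.0023	H26,H33	no
LB	Switzerland, Le Bouillet	46.2781	7.0269					10	0.4667	0.0048	H1,H33	no
LC	Switzerland, Les Collons	46.1799	7.3889					10	0	0	H1	no
LD	Slovenia, Logarska Dolina	46.41	14.636					5	0.4000	0.0041	H26,H39	no
LF	Germany, Linderhof	47.57	10.96					4	0	0	H1	no
LG	Germany, Limburg	50.39	8.07	3	1.0000	0.0125	H1,H12,H33					no
LM1	Switzerland, Les Masses	46.176	7.396	2	1.0000	0.0017	H23,H24	7	0.5238	0.0053	H1,H33,H34	no
LM2	Switzerland, Les Masses	46.23	7.01					4	0.5000	0.0025	H25,H33	no
LO	France, Lopreden	48.5967	-3.97					10	0.2000	0.0003	H1,H4	no
LP	Slovenia, Loka Pri Mengsu	46.1426	14.5533					5	0.9000	0.0068	H3,H26,H28,H30	no
LS	France, Les Palais	43.1080	2.7127					4	0	0	H25	no
LT	Italy, La Thuile	45.717	6.9445					9	0	0	H1	no
MA	Italy, Manerba	45.5588	10.5617	10	0	0	H33					no
MO	Russia, Moscow	55.77	37.79	5	0	0	H1					no
OB	Austria, Oberperfuss	47.2332	11.2443					8	0.2500	0.0030	H1,H18	no
OF	Switzerland, Oberdorf	47.24	7.50					5	0	0	H1	no
OT1	Germany, Ottenhöfen	48.5675	8.1561	8	0.6786	0.0063	H1,H31,H33,H34					no
OT2	Germany, Ottenhöfen	48.5618	8.1437					6	0	0	H1	no
PA	Italy, Partschins	46.6901	11.0607					9	0.2222	0.0004	H3,H5	no
PF1	Switzerland, Pfäffikersee	47.341	8.775	3	0	0	H34					no
PF2	Switzerland, Pfäffikersee	47.336	8.761	6	0.3333	0.0006	H34,H37					no
PG	France, Phalsbourg	48.7506	7.2221					6	0.3333	0.0028	H1,H25	no
PH	Belgium, Philippeville	50.2209	4.647	2	0	0	H1	9	0	0	H1	no
PI	USA, Pittsburgh	40.4367	-79.9481	3	0	0	H39					yes
PL	Slovenia, Planina	45.825	14.248	10	0.6444	0.0078	H27,H33					no
PO	Slovenia, Postojna	45.7769	14.2036	6	0	0	H33					no
PR	Spain, Precendi	43.2692	-5.1391					10	0.6444	0.0018	H26,H32,H33,H35	no
PT	Georgia, Poti	42.1457	41.6974	4	0.6667	0.0057	H15,H16					no
PU	Romania, Putna	47.8682	25.5828	10	0	0	H25					no
RE	Germany, Reinsberg	51.0180	13.3397	10	0	0	H1	4	0.5000	0.0025	H25,H33	no
SC	Spain, Santa Coloma de Farners	41.8581	2.6599					14	0	0	H31	no
SG	Switzerland, St. Gallen	47.36	9.14					8	0.1250	0.0004	H1,H14	no
SH	United Kingdom, Shropshire	52.9361	-3.0239					9	0.3889	0.0014	H1,H12,H13	no
SL	Poland, Słubice	52.3467	14.5806	10	0.7333	0.0019	H1,H3,H6,H10					no
SM	United Kingdom, St. Martins	52.9244	-2.9975					8	0.2500	0.0004	H1,H3	no
SO	United Kingdom, Sonning	51.47	-0.89	3	0	0	H1					no
SZ	Bulgaria, Stara Zagora	42.4428	25.6386	10	0	0	H1					no
TE	Italy, Terres	46.3142	11.02					4	0.5000	0.0025	H17,H19	no
TO	Croatia, Tounj	45.2439	15.3253	6	0	0	H19	5	0.4000	0.0027	H36,H37	no
TR	Turkey, Trabzon	40.935	40.246	3	0.6667	0.0023	H28,H29					no
TS	France, Trebes	43.2049	2.4297					7	0	0	H1	no
TU	Italy, Tuenno	46.3261	11.0114	10	0	0	H26					no
UP1	Sweden, Uppsala	59.8532	17.6408	5	0	0	H1					no
UP2	Sweden, Uppsala	59.8518	17.6288	4	0	0	H1					no
VA	Switzerland, Vallorbe	46.6981	6.3456					6	0.3333	0.0034	H1,H33	no
VR	Canada, Vancouver	49.24	-123.11					5	0	0	H1	yes
WE	Germany, Wehr	47.6388	7.8972	10	0.6222	0.0106	H6,H22,H30	5	0	0	H1	no
WH	United Kingdom, Whitekirk	56.0433	-2.6375	10	0	0	H1	2	0	0	H9	no
WU	Switzerland, Wülflingen	47.52	8.70					6	0.3333	0.0006	H1,H6	no
ZU	Switzerland, Zürich	47.3586	8.5364	10	0.6000	0.0039	H1,H30,H38					no
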