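# Curated 60-compound PFAS identification table (negative-mode LC-HRMS, roe deer liver/muscle study).
# Columns: code, iupac_name, formula, printed_mz ([M-H]- observed, 4 d.p.), printed_ppm (signed mass error),
# diagnostic_ions (semicolon-separated fragment m/z), rt (min), max_area (arbitrary units), confidence_level (Schymanski 1-5).
code	iupac_name	formula	printed_mz	printed_ppm	diagnostic_ions	rt	max_area	confidence_level
1	1,1,1,2,2,3,3,4-Octafluoro-7,7-dimethyl-4-octene	C10H12F8	283.0731	-1.46	71.012;115.247;169.001	12.5	2.7e6	3
2	1,1,1,2,2,3,3,4,4,5,5,6,6-Tridecafluoro-7-pentadecene	C15H17F13	443.1031	-4.2	85.011;318.98;343.976	12.64	3.9e7	3
3	1,1,1,2,2,3,3,4,4,5,5,6,6-Tridecafluorohexadecane	C16H21F13	459.1341	-4.67	141.204;318.979;331.100	13.62	2.5e6	2
4	1,1,1,2,2,3,3,4,4,5,5-Undecafluorononadecane	C19H29F11	465.2001	-4.27	181.201;268.974	8.19	7.2e6	3
5	1,1,1,2,2,3,3,4,4,5,5-Undecafluoropentane	C5HF11	268.9836	2.19	118.978;169.001	13.61	4.3e7	2
6	1,1,1,2,2,3,3,4,4-Nonafluorodocosane	C22H37F9	471.2660	-3.89	71.089;387.1833	10.40	4.9e7	3
7	1,1,1,2,2,3,3-Heptafluorododecane	C12H19F7	295.1306	1.34	275.128;168.987	9.74	4.1e8	3
8	1,1,1,3,3,3-Hexafluoro-2-(trifluoromethyl)propan-2-yl heptafluorobutanoate	C8F16O2	430.9587	3.86	118.96;212.978;218.78	8.46	4.9e6	2
9	1-((3-(Dimethylamino)propyl)amino)-4,4,5,5,6,6,7,7,8,8,9,9,10,10,11,11,12,13,13,13-icosafluoro-12-(trifluoromethyl)tridecan-1-ol	C19H19F23N2O	727.1064	0.88	115.087;129.112;568.963;695.043	11.65	1.0e7	3
10	1-(2-chloro-1,1,2,3,3,3-hexafluoropropoxy)-1,1,2,3,3,3-hexafluoropropan-2-ol	C6HClF12O2	366.9409	2.15	116.996;166.995;232.987;348.949;366.944	17.86	7.4e7	2
11	1-(Difluoromethoxy)-1,1,2,2-tetrafluoro-2-(trifluoromethoxy)ethane	C4HF9O2	250.9767	2.74	84.981;134.986;184.984	18.77	3.4e7	2
12	(Pentafluoroethyl)-(trifluoromethyl)cyclohexane	C9H10F8	269.0577	-2.04	118.989;151.097;201.091	11.82	3.9e8	2
13	1-(Perfluoro-n-hexyl)dodecane	C18H25F13	487.1654	-4.16	318.979	12.46	3.1e7	3
14	1-(Tetradec-1-en-1-yl)perfluorohexane	C20H27F13	513.1809	-4.21	318.979;455.117;493.178	13.63	3.0e7	2
15	1-hydro-pentadecafluoroheptane	C7HF15	368.9772	1.64	168.987;268.982	16.78	1.6e7	2
16	1-sec-Butyl-2-(1,1,2,2-tetrafluoroethoxy)benzene	C12H14F4O	249.0904	-1.49	116.996;133.065;219.043;221.061;233.061	12.98	4.5e7	3
17	12,12,13,13,13-Pentafluorotridecanoic acid	C13H21F5O2	303.1390	0.19	175.058;213.071;283.138	9.18	7.9e7	3
18	1H-Benzimidazole, 5,6-dimethyl-2-(pentafluoroethyl)-	C11H9F5N2	263.0600	-4.8	118.069;243.051	6.85	4.5e8	2
19	1H-Perfluorohexane	C6HF13	318.9804	1.89	101.056;118.987;168.1987	15.65	3.0e7	2
20	2,2,3,3,4,4,5,5,6,6,7,7,8,9,9,9-hexadecafluoro-8-(trifluoromethyl)nonanoic acid	C10HF19O2	512.9610	1.89	168.987;344.987	18.29	1.6e7	2
21	2-(3-(2-chloro-1,1,2,3,3,3-hexafluoropropoxy)-1,1,2,2,3,3-hexafluoropropoxy)-1,1,2,2-tetrafluoroethan-1-ol	C8HClF16O3	482.9300	2.8	67.001;96.991;116.998;182.989;298.977	19.76	9.9e7	3
22	2-(Nonafluorobutyl)benzoic acid	C11H5F9O2	339.0085	3.52	295.0189;339.007	10.22	3.2e7	3
23	2-Ethyl-4-(1,1,1,2,3,3,3-heptafluoropropan-2-yl)-3-[(2-methylpropyl)sulfanyl]benzoic acid	C16H17F7O2S	405.0771	1.49	89.055;207.028;281.044	9.09	4.5e6	3
24	2-Vinylperfluorobutane	C6H3F9	245.0030	4.71	224.998	8.97	1.8e7	2
25	2H-Nonafluorobutane	C4HF9	218.9863	0.38	101.977;118.997;151.087	9.94	2.1e7	2
26	3,4,5,5,6,6,7,7,8,8,9,9,10,10,10-Pentadecafluoro-3-decen-2-one	C10H3F15O	422.9880	2.01	380.9765;404.9765	18.3	3.9e8	2
27	3-((2-chloro-1,1,2,3,3,3-hexafluoropropoxy)difluoromethoxy)-1,1,2,2,3,3-hexafluoropropan-1-ol	C7HClF14O3	432.9323	1.25	67.0001;116.997;166.993;182.999;232.977	18.89	4.2e7	3
28	3-(12,12,13,13,14,14,15,15,15-Nonafluoropentadecyl)-1,2-benzenediol	C21H27F9O2	481.1809	2.94	215.063;323.100;389.072	23.27	3.6e6	3
29	3-(3-(2-chloro-1,1,2,3,3,3-hexafluoropropoxy)-1,1,2,2,3,3-hexafluoropropoxy)-1,1,2,2,3,3-hexafluoropropan-1-ol	C9HClF18O3	532.9271	3.08	182.99;466.933	20.41	2.4e8	3
30	3-(Butylsulfanyl)-2-ethyl-4-(1,1,1,2,3,3,3-heptafluoropropan-2-yl)benzoic acid	C16H17F7O2S	405.0771	1.54	181.033;235.0798;305.024;315.026;361.086	9.43	3.1e6	2
31	3-[Ethyl(perfluoro-1-oxopentyl)amino]-2-hydroxypropyl heptanoate	C17H24F9NO4	476.1503	2.9	109.057;218.986;304.039;346.095;364.061;448.115	11.79	3.2e6	2
32	3-Fluoro-4-{(E)-[4'-(heptafluoropropyl)-4-biphenylyl]diazenyl}phenol	C21H12F8N2O	459.0763	2.93	109.012;373.099;439.069	13.73	5.6e7	3
33	3-Pyridinecarboxamide, N-[4-(nonafluorobutoxy)phenyl]-	C16H9F9N2O2	431.0450	0.66	78.034;104.014;121.041;181.041;403.013;431.044	10.87	5.6e6	2
34	4,4-Bis(trifluoromethyl)-2H,4H-1,3-benzodioxine	C10H6F6O2	271.0192	-2.65	245.004	10.20	5.0e8	3
35	4-[Ethyl(2,2,2-trifluoroethyl)amino]-2-(trifluoromethyl)benzonitrile	C12H10F6N2	295.0685	3.3	168.989;211.995;293.053;295.068	7.61	5.7e7	2
36	5,5,6,6,7,7,8,8,9,9,10,10,10-Tridecafluoro-1-decanol	C10H9F13O	427.0153	3.5	361.026;391.0397	15.06	2.7e6	3
37	5,5,6,6,7,7,8,8,9,9,10,10,11,11,12,12,12-Heptadecafluoro-2-methyl-2-dodecanol	C13H11F17O	505.0463	-0.63	485.040	9.03	9.7e6	3
38	6-(1,1,1,3,3,3-Hexafluoro-2-hydroxypropan-2-yl)-3,5,5-trimethylcyclohex-2-en-1-ol	C12H16F6O2	305.0974	-2.66	123.087;166.997;287.087;303.082	13.55	2.7e7	2
39	6-Chloro-1,1,2,2,3,3,4,4,5,5,6,7-dodecafluoroheptane	C7H3ClF12	348.9671	1.70	328.9596;348.966	9.59	6.8e7	3
40	9,9,10,10,11,11,12,12,12-Nonafluorododecan-1-ol	C12H17F9O	347.1080	4.86	218.986;273.033;327.101	9.37	3.2e7	2
41	Diethyl (3,3,4,4,5,5,6,6,6-nonafluorohexyl)phosphonate	C10H14F9O3P	383.0449	-4.03	106.991;326.943;337.075;355.067	9.26	2.5e7	2
42	Hexadecyl 2,3,3,3-tetrafluoropropanoate	C19H34F4O2	369.2405	-4.69	129.128;144.991;185.023;349.236	11.41	2.1e7	3
43	N-[3-(Dimethylamino)propyl]perfluoro-4-(methyl)cyclohexanecarboxamide N-oxide	C13H13F13N2O2	475.0713	3.4	115.087;117.1033;143.085;145.098	12.14	8.7e6	3
44	N-[3-(Dimethylamino)propyl]perfluorobutanamide	C9H13F7N2O	297.0843	0.02	168.992;211.995;240.026;252.027;277.078	11.92	1.5e8	2
45	N-[3-(Dimethyloxidoamino)propyl]perfluoro-3,7-dioxaoctanamide	C11H13F11N2O4	445.0608	-4.23	115.092;143.089;211.087;359.067;384.014;429.037	10.86	4.6e7	2
46	N-dihydroxyethyl amino propyl-perfluorodecane amide	C17H17F19N2O3	657.0890	4.16	169.098;468.977;511.978;554.0229;613.147;637.097	12.49	6.8e6	2
47	N-dimethylammoniocarboxypropyl-perfluoropropane sulfonamide	C9H13F7N2O4S	377.0405	-1.84	143.083;168.986;232.951;275.993;315.004;333.051	13.80	9.2e6	2
48	Perfluoro-2,2,3,3-tetramethyl butanoic acid	C8HF15O2	412.9674	2.24	193.997;368.978	16.79	2.4e7	3
49	Perfluoro-6-methylheptanesulfonate	C8HF17O3S	498.9319	3.35	168.954;330.158	17.91	8.7e7	2
50	Perfluoro-n-hexanesulfonate	C6HF13O3S	398.9372	1.38	118.472;168.278	15.75	6.3e7	1
51	Perfluoro-n-octanesulfonate	C8HF17O3S	498.9321	3.77	118.232;168.145;218.784	18.26	1.5e8	1
52	Perfluoroheptanesulphonyl fluoride	C7F16O2S	450.9282	-2.02	82.960;368.980;182.970	11.66	1.0e7	2
53	Perfluoro-n-heptanoic acid	C7HF13O2	362.9704	2.27	96.974;318.978	15.65	3.2e7	1
54	Perfluoro-n-hexanoic acid	C6HF11O2	312.9735	2.3	193.97;218.941;268.983	13.61	3.2e7	1
55	Perfluoro-n-nonanoic acid	C9HF17O2	462.9648	3.46	118.997;298.048;318.974	18.28	3.3e7	1
56	Perfluoropropyl formate	C4HF7O2	212.9790	-0.9	94.990;184.984	4.53	3.4e6	2
57	Perfluoro-n-pentanoic acid	C5HF9O2	262.9766	2.15	118.950;143.910;218.990	9.94	1.9e7	1
58	Perfluoro-n-unidecanoic acid	C11HF21O2	562.9583	2.63	116.97;243.97;318.89	20.21	2.0e7	1
59	Pyrifluquinazon	C19H15F7N4O2	463.1013	0.55	103.030;298.047;313.024;443.097	15.49	7.8e6	3
60	2,2,3,3,4,4,5,5,6-nonafluoro-6-oxohexanoic acid	C6HF9O3	290.9723	4.87	168.972;246.971	7.28	3.9e6	3
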