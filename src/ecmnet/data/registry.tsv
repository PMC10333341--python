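index	name	hemisphere	abbreviation	category
0	Frontal Pole	left	FP	cortical
1	Insular Cortex	left	INS	cortical
2	Superior Frontal Gyrus	left	SFG	cortical
3	Middle Frontal Gyrus	left	MFG	cortical
4	Inferior Frontal Gyrus, pars triangularis	left	IFGtri	cortical
5	Inferior Frontal Gyrus, pars opercularis	left	IFGop	cortical
6	Precentral Gyrus	left	PreCG	cortical
7	Temporal Pole	left	TP	cortical
8	Superior Temporal Gyrus, anterior division	left	STGa	cortical
9	Superior Temporal Gyrus, posterior division	left	STGp	cortical
10	Middle Temporal Gyrus, anterior division	left	MTGa	cortical
11	Middle Temporal Gyrus, posterior division	left	MTGp	cortical
12	Middle Temporal Gyrus, temporooccipital part	left	MTGto	cortical
13	Inferior Temporal Gyrus, anterior division	left	ITG	cortical
14	Inferior Temporal Gyrus, posterior division	left	ITGp	cortical
15	Inferior Temporal Gyrus, temporooccipital part	left	ITGto	cortical
16	Postcentral Gyrus	left	PostCG	cortical
17	Superior Parietal Lobule	left	SPL	cortical
18	Supramarginal Gyrus, anterior division	left	SMGa	cortical
19	Supramarginal Gyrus, posterior division	left	SMGp	cortical
20	Angular Gyrus	left	AG	cortical
21	Lateral Occipital Cortex, superior division	left	LOCs	cortical
22	Lateral Occipital Cortex, inferior division	left	LOCi	cortical
23	Intracalcarine Cortex	left	ICC	cortical
24	Frontal Medial Cortex	left	FMC	cortical
25	Juxtapositional Lobule Cortex	left	JLC	cortical
26	Subcallosal Cortex	left	SubCC	cortical
27	Paracingulate Gyrus	left	PaCG	cortical
28	Cingulate Gyrus, anterior division	left	CGa	cortical
29	Cingulate Gyrus, posterior division	left	CGp	cortical
30	Precuneous Cortex	left	PCun	cortical
31	Cuneal Cortex	left	CunC	cortical
32	Frontal Orbital Cortex	left	FOrb	cortical
33	Parahippocampal Gyrus, anterior division	left	PHG	cortical
34	Parahippocampal Gyrus, posterior division	left	PHGp	cortical
35	Lingual Gyrus	left	LG	cortical
36	Temporal Fusiform Cortex, anterior division	left	FFG	cortical
37	Temporal Fusiform Cortex, posterior division	left	FFGp	cortical
38	Temporal Occipital Fusiform Cortex	left	TOFC	cortical
39	Occipital Fusiform Gyrus	left	OFG	cortical
40	Frontal Operculum Cortex	left	FOp	cortical
41	Central Opercular Cortex	left	COp	cortical
42	Parietal Operculum Cortex	left	POp	cortical
43	Planum Polare	left	PP	cortical
44	Heschl's Gyrus	left	HG	cortical
45	Planum Temporale	left	PT	cortical
46	Supracalcarine Cortex	left	SCC	cortical
47	Occipital Pole	left	OP	cortical
48	Frontal Pole	right	FP	cortical
49	Insular Cortex	right	INS	cortical
50	Superior Frontal Gyrus	right	SFG	cortical
51	Middle Frontal Gyrus	right	MFG	cortical
52	Inferior Frontal Gyrus, pars triangularis	right	IFGtri	cortical
53	Inferior Frontal Gyrus, pars opercularis	right	IFGop	cortical
54	Precentral Gyrus	right	PreCG	cortical
55	Temporal Pole	right	TP	cortical
56	Superior Temporal Gyrus, anterior division	right	STGa	cortical
57	Superior Temporal Gyrus, posterior division	right	STGp	cortical
58	Middle Temporal Gyrus, anterior division	right	MTGa	cortical
59	Middle Temporal Gyrus, posterior division	right	MTGp	cortical
60	Middle Temporal Gyrus, temporooccipital part	right	MTGto	cortical
61	Inferior Temporal Gyrus, anterior division	right	ITG	cortical
62	Inferior Temporal Gyrus, posterior division	right	ITGp	cortical
63	Inferior Temporal Gyrus, temporooccipital part	right	ITGto	cortical
64	Postcentral Gyrus	right	PostCG	cortical
65	Superior Parietal Lobule	right	SPL	cortical
66	Supramarginal Gyrus, anterior division	right	SMGa	cortical
67	Supramarginal Gyrus, posterior division	right	SMGp	cortical
68	Angular Gyrus	right	AG	cortical
69	Lateral Occipital Cortex, superior division	right	LOCs	cortical
70	Lateral Occipital Cortex, inferior division	right	LOCi	cortical
71	Intracalcarine Cortex	right	ICC	cortical
72	Frontal Medial Cortex	right	FMC	cortical
73	Juxtapositional Lobule Cortex	right	JLC	cortical
74	Subcallosal Cortex	right	SubCC	cortical
75	Paracingulate Gyrus	right	PaCG	cortical
76	Cingulate Gyrus, anterior division	right	CGa	cortical
77	Cingulate Gyrus, posterior division	right	CGp	cortical
78	Precuneous Cortex	right	PCun	cortical
79	Cuneal Cortex	right	CunC	cortical
80	Frontal Orbital Cortex	right	FOrb	cortical
81	Parahippocampal Gyrus, anterior division	right	PHG	cortical
82	Parahippocampal Gyrus, posterior division	right	PHGp	cortical
83	Lingual Gyrus	right	LG	cortical
84	Temporal Fusiform Cortex, anterior division	right	FFG	cortical
85	Temporal Fusiform Cortex, posterior division	right	FFGp	cortical
86	Temporal Occipital Fusiform Cortex	right	TOFC	cortical
87	Occipital Fusiform Gyrus	right	OFG	cortical
88	Frontal Operculum Cortex	right	FOp	cortical
89	Central Opercular Cortex	right	COp	cortical
90	Parietal Operculum Cortex	right	POp	cortical
91	Planum Polare	right	PP	cortical
92	Heschl's Gyrus	right	HG	cortical
93	Planum Temporale	right	PT	cortical
94	Supracalcarine Cortex	right	SCC	cortical
95	Occipital Pole	right	OP	cortical
96	Thalamus	left	THA	subcortical
97	Caudate nucleus	left	CAU	subcortical
98	Putamen	left	PUT	subcortical
99	Pallidum	left	PAL	subcortical
100	Hippocampus	left	HIP	subcortical
101	Amygdala	left	AMYG	subcortical
102	Accumbens	left	NAcc	subcortical
103	Thalamus	right	THA	subcortical
104	Caudate nucleus	right	CAU	subcortical
105	Putamen	right	PUT	subcortical
106	Pallidum	right	PAL	subcortical
107	Hippocampus	right	HIP	subcortical
108	Amygdala	right	AMYG	subcortical
109	Accumbens	right	NAcc	subcortical
110	Brainstem	midline	BST	brainstem
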