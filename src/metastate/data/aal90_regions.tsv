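label	name
1	L. Amygdala
2	R. Amygdala
3	L. Angular Gyrus
4	R. Angular Gyrus
5	L. Calcarine Fissure
6	R. Calcarine Fissure
7	L. Caudate Nucleus
8	R. Caudate Nucleus
9	L. Ant. Cingulate Cort.
10	R. Ant. Cingulate Cort.
11	L. Mid. Cingulate Cort.
12	R. Mid. Cingulate Cort.
13	L. Pos. Cingulate Cort.
14	R. Pos. Cingulate Cort.
15	L. Cuneus
16	R. Cuneus
17	L. Inf. Frontal Oper.
18	R. Inf. Frontal Oper.
19	L. Inf. Frontal Orbital
20	R. Inf. Frontal Orbital
21	L. Inf. Frontal Triang.
22	R. Inf. Frontal Triang.
23	L. Med. Frontal Orbital
24	R. Med. Frontal Orbital
25	L. Frontal Middle
26	L. Frontal Mid. Orbital
27	R. Mid Frontal Orbital
28	R. Middle Frontal
29	L. Superior Frontal
30	L. Frontal Sup. Med.
31	R. Sup. Frontal Med.
32	L. Sup. Frontal Orbital
33	R. Sup. Frontal Orbital
34	R. Superior Frontal
35	L. Fusiform Gyrus
36	R. Fusiform Gyrus
37	L. Heschl Gyrus
38	R. Heschl Gyrus
39	L. Hippocampus
40	R. Hippocampus
41	L. Insula
42	R. Insula
43	L. Lingual Gyrus
44	R. Lingual Gyrus
45	L. Inf. Occipital Gyrus
46	R. Inf. Occipital Gyrus
47	L. Mid. Occipital Gyrus
48	R. Mid. Occipital Gyrus
49	L. Sup. Occipital Gyrus
50	R. Sup. Occipital Gyrus
51	L. Olfactory Cortex
52	R. Olfactory Cortex
53	L. Pallidum
54	R. Pallidum
55	L. Paracentral Lobule
56	R. Paracentral Lobule
57	L. Parahippocampal
58	R. Parahippocampal
59	L. Inf. Parietal Gyrus
60	R. Inf. Parietal Gyrus
61	L. Sup. Parietal Gyrus
62	R. Sup. Parietal Gyrus
63	L. Postcentral Gyrus
64	R. Postcentral Gyrus
65	L. Precentral Gyrus
66	R. Precentral Gyrus
67	L. Precuneus
68	R. Precuneus
69	L. Putamen
70	R. Putamen
71	L. Rectus Gyrus
72	R. Rectus Gyrus
73	L. Rolandic Operculum
74	R. Rolandic Operculum
75	L. Supplementary Motor Area
76	R. Supplementary Motor Area
77	L. Supramarginal Gyrus
78	R. Supramarginal Gyrus
79	L. Inf. Temporal Gyrus
80	R. Inf. Temporal Gyrus
81	L. Mid. Temporal Gyrus
82	R. Mid. Temporal Gyrus
83	L. Mid. Temporal Pole Gyrus
84	R. Mid. Temporal Pole Gyrus
85	L. Sup. Temporal Pole Gyrus
86	R. Sup. Temporal Pole Gyrus
87	L. Sup. Temporal Gyrus
88	R. Sup. Temporal Gyrus
89	L. Thalamus
90	R. Thalamus
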