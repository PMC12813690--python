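node	name	network
1	PreCG.L	Somatomotor
2	PreCG.R	Somatomotor
3	SFGdor.L	Frontoparietal Control
4	SFGdor.R	Frontoparietal Control
5	ORBsup.L	Limbic
6	ORBsup.R	Limbic
7	MFG.L	Frontoparietal Control
8	MFG.R	Frontoparietal Control
9	ORBmid.L	Limbic
10	ORBmid.R	Limbic
11	IFGoperc.L	Frontoparietal Control
12	IFGoperc.R	Frontoparietal Control
13	IFGtriang.L	Frontoparietal Control
14	IFGtriang.R	Frontoparietal Control
15	ORBinf.L	Limbic
16	ORBinf.R	Limbic
17	ROL.L	Somatomotor
18	ROL.R	Somatomotor
19	SMA.L	Somatomotor
20	SMA.R	Somatomotor
21	OLF.L	Limbic
22	OLF.R	Limbic
23	SFGmed.L	Default Mode
24	SFGmed.R	Default Mode
25	ORBsupmed.L	Default Mode
26	ORBsupmed.R	Default Mode
27	REC.L	Limbic
28	REC.R	Limbic
29	INS.L	Ventral Attention
30	INS.R	Ventral Attention
31	ACG.L	Default Mode
32	ACG.R	Default Mode
33	DCG.L	Ventral Attention
34	DCG.R	Ventral Attention
35	PCG.L	Default Mode
36	PCG.R	Default Mode
37	HIP.L	Subcortical
38	HIP.R	Subcortical
39	PHG.L	Limbic
40	PHG.R	Limbic
41	AMYG.L	Subcortical
42	AMYG.R	Subcortical
43	CAL.L	Visual
44	CAL.R	Visual
45	CUN.L	Visual
46	CUN.R	Visual
47	LING.L	Visual
48	LING.R	Visual
49	SOG.L	Visual
50	SOG.R	Visual
51	MOG.L	Visual
52	MOG.R	Visual
53	IOG.L	Visual
54	IOG.R	Visual
55	FFG.L	Visual
56	FFG.R	Visual
57	PoCG.L	Somatomotor
58	PoCG.R	Somatomotor
59	SPG.L	Dorsal Attention
60	SPG.R	Dorsal Attention
61	IPL.L	Frontoparietal Control
62	IPL.R	Frontoparietal Control
63	SMG.L	Ventral Attention
64	SMG.R	Ventral Attention
65	ANG.L	Default Mode
66	ANG.R	Default Mode
67	PCUN.L	Default Mode
68	PCUN.R	Default Mode
69	PCL.L	Somatomotor
70	PCL.R	Somatomotor
71	CAU.L	Subcortical
72	CAU.R	Subcortical
73	PUT.L	Subcortical
74	PUT.R	Subcortical
75	PAL.L	Subcortical
76	PAL.R	Subcortical
77	THA.L	Subcortical
78	THA.R	Subcortical
79	HES.L	Somatomotor
80	HES.R	Somatomotor
81	STG.L	Ventral Attention
82	STG.R	Ventral Attention
83	TPOsup.L	Limbic
84	TPOsup.R	Limbic
85	MTG.L	Default Mode
86	MTG.R	Default Mode
87	TPOmid.L	Limbic
88	TPOmid.R	Limbic
89	ITG.L	Default Mode
90	ITG.R	Default Mode
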