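channel_id	source_id	detector_id	region	hemisphere	distance_cm
1	1	1	IFG	left	3.0
2	1	2	IFG	left	3.0
3	2	1	IFG	left	3.0
4	2	2	MFG	left	3.0
5	3	2	MFG	left	3.0
6	3	3	SFG	left	3.0
7	3	4	MFG	left	3.0
8	4	3	SFG	left	3.0
9	4	4	SFG	left	3.0
10	4	5	SFG	right	3.0
11	5	4	aPFC	left	3.0
12	5	5	aPFC	left	3.0
13	5	6	aPFC	right	3.0
14	6	5	aPFC	right	3.0
15	6	6	MFG	right	3.0
16	6	7	MFG	right	3.0
17	7	6	SFG	right	3.0
18	7	7	MFG	right	3.0
19	8	6	IFG	right	3.0
20	8	7	IFG	right	3.0
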