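0	140	54	4	-93	-77	-184	-170	-194	-130	0
15.625	125	59	165	1	42	188	91	52	17	0
31.25	23	174	-90	126	68	-199	-43	142	21	1
46.875	-187	105	91	138	-130	-165	145	-192	16	1
62.5	-168	-81	-8	-31	-39	-189	-198	-151	-197	2
78.125	68	10	58	-98	46	105	-47	-16	198	2
93.75	121	192	-49	74	180	60	136	75	81	2
109.375	-45	150	-146	31	88	138	10	-50	-76	1
125	-31	-6	87	155	-171	173	12	-57	69	1
140.625	28	-99	-72	87	37	1	-65	104	-44	0
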