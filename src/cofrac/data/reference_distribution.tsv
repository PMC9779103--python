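# Distinct-protein counts per monomer-MW bin (rows, kDa) and per SEC fraction
# (columns, fraction mean MW in kDa) for a whole liver-lysate SEC run.
# The last two bins are the half-open intervals [501,601) and [601,701).
mw_bin	400	290	130	90	60	48
<11	5	12	1	4	4	2
11-21	33	42	37	18	13	25
21-31	86	75	53	45	34	80
31-41	117	110	55	56	68	84
41-51	93	106	56	54	70	78
51-61	77	88	43	53	59	65
61-71	29	32	25	28	28	29
71-81	22	24	14	14	22	20
81-91	12	10	4	3	7	3
91-101	10	9	10	7	4	5
101-111	11	11	6	9	5	5
111-121	10	3	4	3	5	0
121-131	7	4	5	7	3	4
131-141	4	4	0	0	0	0
141-151	6	5	1	1	1	0
151-176	4	2	1	1	1	1
176-201	4	5	3	1	0	0
201-226	0	0	1	0	1	1
226-251	0	0	0	2	2	1
251-301	8	4	2	1	1	1
301-351	0	0	0	0	0	0
351-401	0	0	0	0	1	0
401-451	0	0	0	0	0	0
451-501	0	0	0	0	0	0
501-601	1	1	0	0	1	1
601-701	1	1	1	1	0	1
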