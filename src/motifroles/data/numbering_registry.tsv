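# motifroles numbering registry
# [motifs]
motif_id	n_edges	edges	roles	provenance
1	2	0->1;0->2	5,13	package-convention
2	2	0->1;1->2	1,4,16	pinned-by-text
3	2	0->2;1->2	2,10	package-convention
4	3	0->1;0->2;1->0	6,7,20	package-convention
5	3	0->1;1->2;2->0	18	pinned-by-text
6	3	0->1;1->0;2->0	3,8,24	package-convention
7	4	0->1;0->2;1->0;1->2	12,21	package-convention
8	4	0->1;0->2;1->0;2->1	19,22,25	package-convention
9	3	0->1;0->2;1->2	11,14,17	pinned-by-text
10	4	0->1;1->0;1->2;2->1	9,28	package-convention
11	4	0->1;1->0;2->0;2->1	15,26	package-convention
12	5	0->1;0->2;1->0;1->2;2->0	23,27,29	package-convention
13	6	0->1;0->2;1->0;1->2;2->0;2->1	30	pinned-by-text
# [roles]
role_id	motif_id	ego_pattern	cross_edges	plurality	required_edges	provenance
1	2	out	1->2	1	0->1;1->2	package-convention
2	3	out	2->1	2	0->1;2->1	package-convention
3	6	out	recip	1	0->1;1->2;2->1	package-convention
4	2	in	2->1	1	1->0;2->1	package-convention
5	1	in	1->2	2	1->0;1->2	package-convention
6	4	in	recip	1	1->0;1->2;2->1	package-convention
7	4	recip	1->2	1	0->1;1->0;1->2	package-convention
8	6	recip	2->1	1	0->1;1->0;2->1	package-convention
9	10	recip	recip	2	0->1;1->0;1->2;2->1	package-convention
10	3	in+in	none	1	1->0;2->0	pinned-by-text
11	9	in+in	1->2	1	1->0;1->2;2->0	package-convention
12	7	in+in	recip	1	1->0;1->2;2->0;2->1	package-convention
13	1	out+out	none	1	0->1;0->2	pinned-by-text
14	9	out+out	1->2	1	0->1;0->2;1->2	pinned-by-text
15	11	out+out	recip	1	0->1;0->2;1->2;2->1	package-convention
16	2	in+out	none	1	0->2;1->0	pinned-by-text
17	9	in+out	1->2	1	0->2;1->0;1->2	package-convention
18	5	in+out	2->1	3	0->2;1->0;2->1	package-convention
19	8	in+out	recip	1	0->2;1->0;1->2;2->1	package-convention
20	4	out+recip	none	1	0->1;0->2;1->0	package-convention
21	7	out+recip	1->2	2	0->1;0->2;1->0;1->2	package-convention
22	8	out+recip	2->1	1	0->1;0->2;1->0;2->1	package-convention
23	12	out+recip	recip	1	0->1;0->2;1->0;1->2;2->1	package-convention
24	6	in+recip	none	1	0->1;1->0;2->0	package-convention
25	8	in+recip	1->2	1	0->1;1->0;1->2;2->0	package-convention
26	11	in+recip	2->1	2	0->1;1->0;2->0;2->1	package-convention
27	12	in+recip	recip	1	0->1;1->0;1->2;2->0;2->1	package-convention
28	10	recip+recip	none	1	0->1;0->2;1->0;2->0	pinned-by-text
29	12	recip+recip	1->2	1	0->1;0->2;1->0;1->2;2->0	package-convention
30	13	recip+recip	recip	3	0->1;0->2;1->0;1->2;2->0;2->1	pinned-by-text
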