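serial	strain	rearrangement	n_conidial_derivatives	n_self_sterile	n_mat_a	n_mat_A	genotype	footnote
1	1E1	EB4	67	25	0	25	[Df a + Dp A]	.
2	2E1	EB4	38	10	5	5	[N a + T A]	.
3	3E1	EB4	28	6	6	0	[T a + Df A]	a
4	4E1	EB4	85	12	1	11	[T a + N A]	.
5	6E1	EB4	129	30	10	20	[T a + N A]	.
6	9E1	EB4	62	14	0	14	[Df a + Dp A]	.
7	12E1	EB4	49	16	16	0	[Dp a + Df A]	.
8	13E1	EB4	16	0	0	0	ND	.
9	1(6E1)	EB4	59	9	4	5	ND	.
10	3(6E1)	EB4	63	7	0	7	[Df a + Dp A]	.
11	4(6E1)	EB4	54	10	4	6	ND	.
12	1(9E1)	EB4	40	8	6	2	[T a + N A]	.
13	2(9E1)	EB4	56	10	0	10	ND	.
14	3(9E1)	EB4	65	11	8	3	ND	.
15	I1	IBj5	87	17	8	0	[Dp a + Df A]	.
16	I2	IBj5	75	6	0	6	[Df a + N A]	b
17	I3	IBj5	27	5	0	5	[Df a + T A]	c
18	I4	IBj5	121	34	2	8	[T a + N A]	.
19	I5	IBj5	62	23	4	0	[Dp a + Df A]	.
20	1I1	IBj5	50	4	0	4	[T a + N A]	d
21	2I1	IBj5	24	16	16	0	[Dp a + Df A]	.
22	3I1	IBj5	60	9	2	7	[T a + N A + Df A]	e
23	4I1	IBj5	26	0	0	0	ND	.
24	1I4	IBj5	30	1	0	1	[? a + T A]	f
25	2I4	IBj5	30	18	9	9	[T a + N A]	.
26	U9	UK14-1	24	5	1	4	[T a + N A]	.
27	1U9	UK14-1	19	8	8	0	[Dp a + Df A]	.
28	2U9	UK14-1	49	9	1	8	ND	.
29	3U9	UK14-1	56	7	5	2	ND	.
30	4U9	UK14-1	80	0	0	0	ND	.
31	5U9	UK14-1	44	8	3	5	[N a + T A]	.
32	1(1U9)	UK14-1	0	0	0	0	ND	.
33	2(1U9)	UK14-1	45	12	3	9	[N a + T A]	.
34	3(1U9)	UK14-1	10	10	0	10	[Df a + Dp A]	.
35	B7	B362i	10	10	10	0	[Dp a + Df A]	.
36	11B7	B362i	30	30	30	0	[Dp a + Df A]	.
37	18B7	B362i	20	20	20	0	[Dp a + Df A]	.
38	19B7	B362i	11	8	3	5	[N a + T A]	.
39	24B7	B362i	7	7	7	0	[Dp a + Df A]	.
40	28B7	B362i	33	33	33	0	[Dp a + Df A]	.
41	30B7	B362i	6	6	6	0	[Dp a + Df A]	.
42	31B7	B362i	0	0	0	0	ND	.
43	6(19B7)	B362i	11	11	11	0	[Dp a + Df A]	.
44	1[6(19B7)]	B362i	4	3	2	1	[N a + Dp A]	.
45	2[6(19B7)]	B362i	9	7	2	5	[N a + T A]	.
46	4[6(19B7)]	B362i	24	1	0	1	[? a + T A]	h
47	5[6(19B7)]	B362i	15	14	12	2	[N a + T A]	g
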