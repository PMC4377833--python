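case	BAT25_ngs	BAT25_pcr	BAT26_ngs	BAT26_pcr	D5S346_ngs	D5S346_pcr	BAT34c4_ngs	BAT34c4_pcr	D18S55_ngs	D18S55_pcr	ngs_status	pcr_status
1	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
2	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
3	+	+	+	+	+	+	+	NA	-	NA	High	High
4	+	+	+	+	+	+	+	NA	+	NA	High	High
5	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
6	+	+	+	+	-	-	-	NA	+	NA	High	High
7	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
8	+	+	+	+	+	+	+	NA	+	NA	High	High
9	+	+	+	+	-	-	-	NA	-	NA	High	High
10	+	+	+	+	-	-	+	NA	+	NA	High	High
11	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
12	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
13	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
14	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
15	+	+	+	+	-	-	+	NA	+	NA	High	High
16	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
17	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
18	+	+	+	+	-	+	+	NA	-	NA	High	High
19	+	+	+	+	+	+	+	NA	+	NA	High	High
20	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
21	-	-	-	-	-	-	-	NA	+	NA	Low	Stable
22	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
23	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
24	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
25	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
26	+	+	+	+	+	+	-	NA	+	NA	High	High
27	+	+	+	+	-	-	+	NA	+	NA	High	High
28	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
29	+	+	+	+	-	-	+	NA	-	NA	High	High
30	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
31	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
32	+	+	+	+	-	+	-	NA	-	NA	High	High
33	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
34	+	+	+	+	-	+	+	NA	-	NA	High	High
35	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
36	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
37	+	+	+	+	+	-	+	NA	+	NA	High	High
38	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
39	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
40	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
41	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
42	+	+	+	+	+	+	+	NA	-	NA	High	High
43	+	+	+	+	+	-	+	NA	+	NA	High	High
44	-	-	-	-	-	-	-	NA	-	NA	Stable	Stable
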