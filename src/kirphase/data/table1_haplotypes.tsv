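#loci:	g1	g2	g3	g4	g5	g6	g7	g8	g9	g10	g11	g12	g13	g14
1	0.552	1	0	0	1	0	1	1	0	1	0	0	0	0	1
2	0.003	1	1	1	0	0	0	1	0	1	1	0	0	0	1
3	0.015	1	1	1	0	0	1	1	0	1	1	0	0	0	1
4	0.006	1	0	0	1	0	1	1	1	0	0	0	0	0	1
5	0.101	1	1	1	0	0	0	1	0	1	0	0	0	0	1
6	0.037	1	1	1	0	1	1	1	1	0	1	1	0	1	1
7	0.028	1	1	1	0	0	0	1	1	0	1	0	1	1	1
8	0.064	1	1	1	0	1	1	1	0	1	0	1	0	0	1
9	0.107	1	0	0	1	0	1	1	1	0	1	0	1	1	1
10	0.003	1	0	0	1	1	0	1	1	0	1	1	1	1	1
11	0.015	1	1	1	0	1	1	1	1	0	0	1	0	0	1
12	0.018	1	0	0	1	1	1	1	1	0	0	1	0	1	1
13	0.003	1	0	0	1	0	1	1	0	1	0	0	0	1	1
14	0.006	1	1	1	0	0	1	1	0	1	1	1	0	0	1
15	0.006	1	1	1	0	0	0	1	0	1	1	0	1	1	1
16	0.022	1	1	1	0	0	1	1	0	1	0	0	0	0	1
17	0.012	1	1	1	0	1	0	1	1	0	1	1	1	1	1
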