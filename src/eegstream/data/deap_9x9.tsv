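# DEAP 32-channel montage on a 9x9 scalp grid.
# columns: channel (1-based)	row (0-based, 0 = frontal)	col (0-based)	name (optional)
1	0	3
17	0	5	Fp2
2	1	3
18	1	5
4	2	0
3	2	2
19	2	4
20	2	6
21	2	8
5	3	1
6	3	3
23	3	5
22	3	7
8	4	0
7	4	2
24	4	4
25	4	6
26	4	8
9	5	1
10	5	3	CP1
28	5	5	CP2
27	5	7
12	6	0
11	6	2
16	6	4	Pz
29	6	6
30	6	8
13	7	3	PO3
31	7	5	PO4
14	8	3
15	8	4	Oz
32	8	5
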