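# Published diploid blueberry high-density bin map: per-linkage-group summary
lg	n_bins	n_snps	length_cm	n_gaps_gt10
1	91	1680	116.74	1
2	62	1287	131.21	3
3	85	1764	156.26	3
4	77	1466	101.91	1
5	119	2377	175.47	3
6	85	1779	127.48	2
7	87	1452	134.52	2
8	60	521	126.19	2
9	72	1247	137.41	2
10	50	1006	105.13	2
11	27	344	102.92	3
12	107	2563	124.14	1
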