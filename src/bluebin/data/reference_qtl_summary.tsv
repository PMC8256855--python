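# Published diploid blueberry QTLs supported by >= 2 years of phenotypes.
# Multi-QTL table rows (two LGs in one printed row) are expanded to one
# record per QTL; trait heritability is filled down within a trait.
trait	year	cutoff_lod	peak_lod	lg	bin_first	bin_last	h2	r2	r2_over_h2
ChillReq	2011	13.64	25.95	5	113	119	0.86	0.30	0.35
ChillReq	2012	12.99	37.26	5	113	119	0.86	0.30	0.35
ChillReq	2013	9.00	49.22	5	113	119	0.86	0.40	0.47
ColdHard	2009	9.59	21.85	10	32	36	0.88	0.27	0.31
ColdHard	2010	11.22	17.31	10	32	36	0.88	0.22	0.25
Color	2012	13.08	30.50	2	20	32	0.80	0.38	0.48
Color	2013	8.46	22.84	2	20	32	0.80	0.25	0.31
Color	2013	8.46	22.84	10	18	25	0.80	0.18	0.23
Color	2015	7.68	16.80	2	20	32	0.80	0.21	0.26
Color	2015	7.68	16.80	10	18	25	0.80	0.39	0.49
Color	2017	9.78	11.64	2	20	32	0.80	0.13	0.16
Scar	2018	6.18	9.21	12	79	80	0.67	0.11	0.16
Scar	2019	11.40	19.00	12	79	80	0.67	0.44	0.66
20SFirm	2017	6.64	16.06	6	4	10	0.47	0.42	0.89
20SFirm	2019	15.42	17.04	6	4	10	0.47	0.63	1.00
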