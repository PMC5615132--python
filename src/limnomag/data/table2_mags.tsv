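# Summary table for the 19 freshwater Verrucomicrobia MAG cohort (manually transcribed).
# Coverage statistics were computed from the 94 (ME), 45 (TE) or 45 (TH) per-group metagenomes.
genome_id	img_taxon_oid	subdivision	size_mbp	completeness_pct	contamination_pct	gc_pct	coding_pct	gene_count	cov_median	cov_mean	cov_cv_pct
ME3880	2582580573	1	1.6	70	2	58	90.9	1585	0.2	2.9	217
TH2746	2582580664	1	6.5	81	3	62	86.7	5430	3.3	4.7	82
ME12612	2582580523	1	2.2	79	3	59	89.0	2335	0.0	0.9	261
ME12173	2582580521	1	2.1	63	3	52	91.3	2070	0.0	0.8	583
TE4605	2582580638	1	4.7	91	0	59	91.1	4380	1.0	4.8	198
ME6381	2582580593	1	2.4	62	0	57	92.5	2221	0.0	0.4	285
ME8366	2582580607	2	3.6	87	5	63	87.4	3450	0.0	1.2	326
TH2747	2582580665	3	5.2	93	8	58	89.6	4846	1.8	2.8	99
TH3004	2582580668	3	4.5	93	6	57	91.4	3798	1.9	5.8	139
TH0989	2556921153	3	7.2	91	8	62	90.3	5583	6.1	6.3	61
TH2519	2593339181	4	1.8	69	2	42	94.3	1654	6.2	6.7	60
TE1800	2593339189	4	2.2	84	2	42	94.3	1998	10.8	11.3	77
TH4590	2582580688	4	3.3	87	1	65	90.7	3132	2.4	3.6	99
ME2014	2582580546	4	1.9	77	5	66	93.7	1700	1.0	3.3	174
ME12657	2582580524	4	1.9	81	7	68	94.0	1838	0.0	0.8	344
TE1301	2582580616	4	2.0	95	0	54	94.7	1943	4.1	14.2	187
TH4093	2582580682	unclassified	4.7	77	6	48	86.5	3982	4.3	3.9	61
ME30509	2582580559	unclassified	1.2	51	2	63	92.3	1160	0.0	0.5	479
TH4820	2582580691	unclassified	3.0	56	3	63	86.7	2794	1.0	2.1	110
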