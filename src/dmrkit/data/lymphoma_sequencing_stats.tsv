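sample_id	group	sequenced_reads	data_gbp	mapped_reads	mapping_rate_pct	dedup_reads	dup_pct	conversion_rate
D15	lymphoma	1471119044	220.7	942210058	64.05	921179226	2.2	0.99
D16	lymphoma	1374040624	206.1	880626330	64.09	846436780	3.9	0.99
D18	lymphoma	1621119906	243.2	986042610	60.82	921278317	6.6	0.99
D19	lymphoma	1488384704	223.3	599523524	40.28	498068081	16.9	0.99
D20	lymphoma	1335235072	200.3	888439718	66.54	872186632	1.8	0.99
D21	lymphoma	1504685636	225.7	609850737	40.53	506837326	16.9	0.99
D22	lymphoma	1440045372	216.0	650928388	45.20	557306630	14.4	0.99
D23	lymphoma	1661628566	249.2	752672493	45.30	624967698	17.0	0.99
D24	lymphoma	1458733410	218.8	583552483	40.00	478893383	17.9	0.99
D25	lymphoma	1630311074	244.5	658822764	40.41	533411778	19.0	0.99
D28	lymphoma	1432433688	214.9	915182746	63.89	898509744	1.8	0.99
D29	lymphoma	1360933072	204.1	889512076	65.36	871747385	2.0	0.99
D30	lymphoma	1370910340	205.6	887239964	64.72	869797915	2.0	0.99
D31	lymphoma	1431411718	214.7	897085424	62.67	879039244	2.0	0.99
D32	lymphoma	1311901762	196.8	851540570	64.91	837617920	1.6	0.99
D36	lymphoma	1442345274	216.4	921197632	63.87	901449651	2.1	0.99
D37	lymphoma	1470580534	220.6	887838444	60.37	868419348	2.2	0.99
D38	lymphoma	1505734980	225.9	942032752	62.56	923800492	1.9	0.99
D39	lymphoma	1582775108	237.4	981349414	62.00	960294884	2.1	0.99
D40	lymphoma	1446427318	217.0	897388910	62.04	881112307	1.8	0.99
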