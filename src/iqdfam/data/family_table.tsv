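gene_name	sequence_id	chromosome	location	orf_length_bp	pi	mw_da	size_aa	exons
PeIQD1	PH01000003G1440	PH01000003	967133-969487 (+stand)	1581	10.97	56786.68	526	5
PeIQD2	PH01000025G1940	PH01000025	1440447-1445151 (+stand)	1164	10.12	40499.31	387	3
PeIQD3	PH01000047G0550	PH01000047	413725-417652 (+stand)	1284	10.21	47172.98	427	6
PeIQD4	PH01000048G0670	PH01000048	465999-469782 (-stand)	1215	10.8	44104.8	404	4
PeIQD5	PH01000057G1170	PH01000057	819186-824476 (+stand)	2574	5.02	94051.68	857	2
PeIQD6	PH01000062G1950	PH01000062	1326243-1328709 (+stand)	573	7.97	20417.05	190	5
PeIQD7	PH01000208G0940	PH01000208	774898-778391 (+stand)	1359	10.03	49944.89	452	5
PeIQD8	PH01000232G0210	PH01000232	100923-106341 (-stand)	1410	10.31	51361.34	469	5
PeIQD9	PH01000241G1120	PH01000241	727425-732816 (+stand)	2100	11.12	75521.94	699	6
PeIQD10	PH01000252G0640	PH01000252	542193-546553 (+stand)	1131	10.59	42409.3	376	3
PeIQD11	PH01000271G0580	PH01000271	407684-415256 (-stand)	1665	9.63	61112.7	554	5
PeIQD12	PH01000284G0220	PH01000284	125209-128867 (+stand)	1122	10.29	41965.83	373	3
PeIQD13	PH01000358G0650	PH01000358	525937-527963 (-stand)	1377	10.58	49279.03	458	3
PeIQD14	PH01000428G0560	PH01000428	373345-378158 (-stand)	1422	10.09	52057.07	473	5
PeIQD15	PH01000458G0650	PH01000458	459032-464703 (+stand)	1050	7.23	38832.77	349	5
PeIQD16	PH01000502G0350	PH01000502	306474-312052 (+stand)	1782	9.52	65347.29	593	5
PeIQD17	PH01000742G0510	PH01000742	312291-319680 (+stand)	2823	8.99	105765.41	940	5
PeIQD18	PH01001210G0100	PH01001210	52102-56165 (+stand)	1701	9.75	62065.3	566	6
PeIQD19	PH01001453G0160	PH01001453	91365-97487 (+stand)	1320	9.59	48644.97	439	6
PeIQD20	PH01001731G0460	PH01001473	186745-189760 (-stand)	1074	10.52	39918.54	357	3
PeIQD21	PH01001473G0280	PH01001731	279500-284408 (+stand)	1824	9.56	67194.21	607	5
PeIQD22	PH01002085G0100	PH01002085	37695-40080 (-stand)	873	5.16	32027.29	290	1
PeIQD23	PH01002634G0120	PH01002634	70363-76783 (-stand)	1023	9.3	38307.17	340	6
PeIQD24	PH01003208G0200	PH01003208	131125-135457 (+stand)	1416	10.05	51559.67	471	5
PeIQD25	PH01003304G0090	PH01003304	40750-43396 (-stand)	1083	10.35	40194.03	360	3
PeIQD26	PH01003925G0040	PH01003925	40308-47140 (+stand)	2769	5.1	101962.98	922	5
PeIQD27	PH01004272G0030	PH01004272	8090-9565 (-stand)	894	10.77	31984.13	297	5
PeIQD28	PH01004403G0090	PH01004403	68879-71552 (-stand)	1461	10.5	54111.89	486	3
PeIQD29	PH01004470G0050	PH01004470	15995-19170 (+stand)	1305	10.38	46928.34	434	3
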