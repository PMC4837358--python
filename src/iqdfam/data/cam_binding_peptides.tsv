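group	gene_name	start_1based	peptide
I	PeIQD1	3	KGGTSWLTAVKRAFRSP
I	PeIQD1	145	ALKGLVKLQALVRGHNV
I	PeIQD1	261	QTRKDAALKRERALSYAF
I	PeIQD2	130	SAIKIQSAFRSYLARKALCA
I	PeIQD7	426	RIRKRIWEGGICRIQS
I	PeIQD10	92	VVIQKSFRGYLARK
I	PeIQD12	9	KKLLTGRKGGHKGLK
I	PeIQD13	183	ALVRAQAAIRAARSR
I	PeIQD20	8	AAVMIQKAFRGYLARKALRA
I	PeIQD20	103	SLVKLQALVRGYLVRKQAVT
I	PeIQD25	85	SAVMIQKAFKGYLARKALRA
I	PeIQD25	107	SLVKLQALVRGYLVRKQAAT
I	PeIQD27	143	GNAKLGRR
I	PeIQD29	151	VKMQALVRGHLVRRQAS
I	PeIQD29	172	MQALVAAQNRARAARLR
II	PeIQD3	151	QAVRRQTAATLRGLESLVKIQ
III	PeIQD4	38	SGGQRGAAAGNASA
III	PeIQD8	215	QEAGIRRERALAYAF
III	PeIQD9	466	SFLLSLMRAAAS
III	PeIQD14	216	EAAIRRERALAYAFS
III	PeIQD15	165	FRAFLARRARRALKGL
III	PeIQD19	156	ARVRARQVRVTLE
III	PeIQD23	6	SKWIKSLIGIRKQEKG
III	PeIQD23	125	IVKLQALVRGHIVRKQTA
III	PeIQD23	151	LVRAQARVRARQVRVAL
III	PeIQD24	213	QGAAIRRERSLAYAF
III	PeIQD28	191	RGLVRLKSLVDGNTVKR
IV	PeIQD5	248	KLQAVIRGHLVRRQAAESLQ
IV	PeIQD6	118	AVREARRAVTRRVVGLQE
IV	PeIQD11	166	FQALVRGRNVRLS
IV	PeIQD16	194	FQALVRGRNVRLSS
IV	PeIQD17	598	EYHNLKKAISIL
IV	PeIQD17	655	RFVRMRRSAIVIQQAVR
IV	PeIQD18	16	QALVRGRNVRLSS
IV	PeIQD21	145	LVRRQSVSTLRATLLIVKFQALV
IV	PeIQD21	195	KSS
IV	PeIQD22	227	ERALAYAFSQKL
IV	PeIQD26	259	KLQAVIRGHLVRRQAAESLQ
IV	PeIQD26	893	SNRGTFIYLLAQWRIC
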