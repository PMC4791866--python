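sample_id	germline_group	histology	grade	ER	PR	HER2	her2_ihc_score	BRCA1_IHC	survival_time	event
T6	BRCAX	IDC	III	negative	negative	negative	0	negative	NA	NA
T10	BRCAX	IDC	III	negative	negative	negative	0	negative	NA	NA
T11	BRCAX	IDC	III	negative	negative	negative	0	negative	NA	NA
T12	BRCAX	IDC	II	negative	positive	negative	0	negative	NA	NA
T17	BRCAX	IDC	III	negative	negative	negative	0	negative	NA	NA
T20	BRCAX	LCIS	NA	negative	negative	negative	1+	negative	NA	NA
T24	BRCA1	IDC	II	negative	negative	negative	0	negative	NA	NA
T39	BRCAX	IDC	III	negative	negative	negative	0	negative	NA	NA
T41	BRCAX	IDC	III	negative	negative	negative	0	negative	NA	NA
T42	BRCAX	IDC	III	negative	negative	negative	0	negative	NA	NA
T43	BRCAX	IDC	III	negative	negative	negative	0	negative	NA	NA
T45	BRCAX	IDC	II	negative	positive	negative	0	negative	NA	NA
T25	BRCA1	IDC	III	positive	positive	negative	0	negative	NA	NA
T1	BRCAX	IDC	III	positive	negative	negative	1+	negative	NA	NA
T3	BRCAX	IDC	III	positive	positive	negative	0	negative	NA	NA
T26	BRCAX	IDC	III	positive	positive	negative	0	negative	NA	NA
T29	BRCAX	IDC	II	positive	positive	negative	1+	negative	NA	NA
T32	BRCAX	IDC	I	positive	positive	negative	0	negative	NA	NA
T35	BRCAX	IDC	I	positive	positive	negative	0	negative	NA	NA
T36	BRCAX	IDC	I	positive	positive	negative	0	negative	NA	NA
T37	BRCAX	IDC	II	positive	positive	negative	0	negative	NA	NA
T9	BRCAX	LCIS	NA	positive	positive	positive	3+	negative	NA	NA
T15	BRCAX	IDC	II	positive	positive	positive	2+	negative	NA	NA
T21	BRCAX	ILC	NA	positive	positive	positive	2+	negative	NA	NA
T4	BRCAX	IDC	I	negative	positive	negative	0	positive	NA	NA
T5	BRCA2	IDC	III	negative	negative	negative	0	positive	NA	NA
T16	BRCAX	IDC	I	negative	positive	negative	0	positive	NA	NA
T23	BRCAX	IDC	III	negative	negative	negative	0	positive	NA	NA
T19	BRCAX	LCIS	NA	negative	positive	positive	2+	positive	NA	NA
T46	BRCAX	IDC	III	negative	negative	positive	3+	positive	NA	NA
T44	BRCA2	DCIS	NA	positive	positive	negative	0	positive	NA	NA
T49	BRCA1	IDC	II	positive	positive	negative	0	positive	NA	NA
T2	BRCAX	DCIS	NA	positive	positive	negative	0	positive	NA	NA
T8	BRCAX	ILC	NA	positive	negative	negative	0	positive	NA	NA
T13	BRCAX	DCIS	NA	positive	positive	negative	0	positive	NA	NA
T22	BRCAX	IDC	II	positive	positive	negative	0	positive	NA	NA
T28	BRCAX	DCIS	NA	positive	positive	negative	1+	positive	NA	NA
T30	BRCAX	ILC	NA	positive	positive	negative	1+	positive	NA	NA
T31	BRCAX	IDC	I	positive	positive	negative	0	positive	NA	NA
T33	BRCAX	IDC	III	positive	positive	negative	0	positive	NA	NA
T34	BRCAX	IDC	II	positive	positive	negative	0	positive	NA	NA
T38	BRCAX	LCIS	NA	positive	positive	negative	0	positive	NA	NA
T47	BRCAX	IDC	II	positive	positive	negative	0	positive	NA	NA
T48	BRCAX	IDC	III	positive	negative	negative	0	positive	NA	NA
T14	BRCAX	DCIS	NA	positive	positive	positive	2+	positive	NA	NA
T51	BRCA2	IDC	II	positive	positive	unknown	ND	unknown	NA	NA
T50	BRCA2	IDC	III	positive	negative	negative	1+	unknown	NA	NA
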