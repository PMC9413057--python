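patient_id	center	sex	age	driver_status	pdl1_tps	treatment	line	recist	pfs_months	pfs_status	os_months	os_status
rASC-01	Center 1	Male	67	Wild type	<1%	Immunotherapy+chemotherapy	1	SD	3.0	0	4.0	0
rASC-02	Center 1	Male	62	Wild type	NA	Immunotherapy+chemotherapy	>=3	PR	24.0	1	25.0	0
rASC-03	Center 2	Male	64	EGFR exon 19 deletion	<1%	Immunotherapy+chemotherapy	>=3	SD	5.4	1	18.4	0
rASC-04	Center 2	Male	61	Wild type	1%	Immunotherapy+chemotherapy	1	PD	1.6	1	13.4	1
rASC-05	Center 2	Female	61	MET exon 14 skipping	5%	Immunotherapy	>=3	PR	5.3	1	24.7	1
rASC-06	Center 2	Male	61	Wild type	40%	Immunotherapy	1	SD	11.5	0	11.5	0
rASC-07	Center 2	Male	74	Wild type	20%	Immunotherapy+chemotherapy	2	PR	15.6	0	15.6	0
rASC-08	Center 3	Male	77	RET fusion	NA	Immunotherapy	>=3	PD	1.3	1	10.7	1
rASC-09	Center 3	Male	64	Wild type	2%	Immunotherapy+chemotherapy	2	PD	2.5	1	2.6	0
rASC-10	Center 4	Male	63	NA	15%	Immunotherapy+chemotherapy	1	SD	20.9	0	20.9	0
rASC-11	Center 4	Male	68	KRAS	NA	Immunotherapy+chemotherapy	2	PD	0.7	1	16.4	1
rASC-12	Center 4	Female	47	Wild type	<1%	Immunotherapy+chemotherapy	1	PD	6.6	1	6.6	0
rASC-13	Center 4	Male	51	Wild type	NA	Immunotherapy	2	PR	1.4	1	1.4	1
rASC-14	Center 4	Male	43	Wild type	NA	Immunotherapy	2	SD	15.6	1	52.3	0
rASC-15	Center 4	Male	54	Wild type	NA	Immunotherapy+chemotherapy	1	SD	6.0	1	11.9	1
rASC-16	Center 4	Female	78	Wild type	NA	Immunotherapy	2	SD	24.0	1	44.9	0
rASC-17	Center 4	Male	60	Wild type	NA	Immunotherapy+chemotherapy	>=3	SD	7.9	1	22.7	0
rASC-18	Center 4	Male	57	KRAS	<1%	Immunotherapy	2	SD	30.2	0	30.2	0
rASC-19	Center 4	Male	68	Wild type	NA	Immunotherapy	1	SD	25.6	1	33.6	0
rASC-20	Center 5	Male	54	NA	NA	Immunotherapy	2	PD	2.6	1	6.0	1
rASC-21	Center 5	Female	50	NA	NA	Immunotherapy+chemotherapy	>=3	SD	1.9	1	12.7	0
rASC-22	Center 5	Female	60	NA	NA	Immunotherapy	2	PD	0.7	1	6.4	0
rASC-23	Center 5	Female	43	NA	NA	Immunotherapy+chemotherapy	1	SD	5.1	1	8.6	0
rASC-24	Center 5	Male	55	NA	NA	Immunotherapy	2	PD	1.3	1	15.4	1
rASC-25	Center 5	Male	82	NA	NA	Immunotherapy	1	PD	0.7	1	0.7	0
rASC-26	Center 6	Male	53	NA	>=50%	Immunotherapy+chemotherapy	>=3	SD	8.4	0	14.5	0
rASC-27	Center 6	Female	50	NA	NA	Immunotherapy+chemotherapy	>=3	PR	7.0	1	7.7	1
rASC-28	Center 6	Female	66	EGFR L858R+T790M	NA	Immunotherapy+chemotherapy	>=3	PR	18.8	0	26.1	0
rASC-29	Center 7	Male	59	NA	NA	Immunotherapy+chemotherapy	2	SD	6.4	0	6.4	0
rASC-30	Center 7	Male	48	NA	NA	Immunotherapy+chemotherapy	>=3	SD	3.3	1	18.7	0
rASC-31	Center 8	Female	68	NA	NA	Immunotherapy	2	PR	16.0	1	16.3	1
rASC-32	Center 8	Female	61	NA	NA	Immunotherapy+chemotherapy	1	PR	3.5	1	15.1	1
rASC-33	Center 8	Male	54	NA	NA	Immunotherapy	>=3	SD	2.0	0	2.0	0
rASC-34	Center 8	Female	51	NA	NA	Immunotherapy+chemotherapy	1	PR	8.0	1	10.7	0
rASC-35	Center 8	Male	63	NA	NA	Immunotherapy+chemotherapy	2	SD	11.2	1	11.2	0
rASC-36	Center 9	Male	55	Wild type	NA	Immunotherapy+chemotherapy	>=3	PD	1.5	1	1.5	0
rASC-37	Center 9	Female	68	EGFR L858R+T790M	NA	Immunotherapy	2	PD	0.7	1	1.5	1
rASC-38	Center 9	Male	52	NA	NA	Immunotherapy+chemotherapy	1	SD	5.0	1	6.7	0
rASC-39	Center 9	Female	61	ALK fusion	NA	Immunotherapy+chemotherapy	>=3	PD	1.5	1	1.5	1
rASC-40	Center 10	Female	53	Wild type	90%	Immunotherapy	1	PR	1.7	0	5.9	0
rASC-41	Center 10	Male	58	Wild type	15%	Immunotherapy+chemotherapy	1	PR	5.1	1	7.3	0
rASC-42	Center 10	Male	65	NA	70%	Immunotherapy	1	PR	9.8	1	36.1	1
rASC-43	Center 10	Female	33	EGFR R831H	60%	Immunotherapy	>=3	PD	0.7	1	0.7	0
rASC-44	Center 11	Male	62	KRAS	60%	Immunotherapy	1	PR	15.7	0	16.5	0
rASC-45	Center 11	Male	50	Wild type	>=50%	Immunotherapy	>=3	SD	6.0	1	7.1	1
rASC-46	Center 11	Male	78	Wild type	20%	Immunotherapy+chemotherapy	1	SD	6.8	1	7.0	0
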