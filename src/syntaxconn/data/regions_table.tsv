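name	side	network	x	y	z	additional	brodmann
L_F3op/F3t	L	I	-45	18	27	0	44/45
L_IPS	L	I	-21	-72	51	0	7/39/40
L_IPS/AG	L	I	-33	-58	35	1	7/39
R_IPS/AG	R	I	36	-58	41	1	7/39
R_LPMC	R	I	30	3	45	0	6/8
R_F3op/F3t	R	I	33	18	24	0	44/45
pre-SMA	M	I	9	24	51	0	6/8
R_pSTG/MTG	R	I	60	-57	3	0	22/21
L_LPMC	L	II	-48	3	42	0	6/8
L_AG	L	II	-33	-60	18	0	39
LG	M	II	-3	-69	6	0	18
Cerebellar_nuclei	M	II	-3	-51	-27	0
R_Cerebellum	R	II	27	-64	-34	1
Midbrain	M	II	-6	-19	-13	1
L_F3t	L	III	-48	33	6	0	45
L_F3O	L	III	-36	15	-6	0	47
R_F3O	R	III	30	29	-1	1	47
L_pSTG/MTG	L	III	-57	-48	0	0	22/21
L_pMTG/ITG	L	III	-45	-69	0	0	37/19
L_pITG	L	IV	-45	-49	-22	1	37/19
L_LG/FG	L	IV	-24	-85	-19	1	18/19
R_LG/FG	R	IV	24	-85	-13	1	18/19
Cuneus/Precuneus	M	IV	-6	-76	35	1	7/18/19
L_Caudate/Putamen	L	IV	-15	8	5	1
Thalamus	M	IV	-9	-16	5	1
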