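rsid	gene	protein_change	consequence	variant_class	allele_frequency	allele_count	hom_count	male	female	polyphen2_class	polyphen2_score	grantham	provean	sift	phastcons	gerp
rs148814027	NUP155	V402M	missense	snv	0.000704		0			probably-damaging	0.971	21	-3.24	0.004	1	5.68
rs371676330	NUP155	P607L	missense	snv	0.000016		0			probably-damaging	0.975	98	-2.16	0.008	0.985	5.07
rs200783324	NUP155	G716R	missense	snv	0.000035		0			probably-damaging	0.984	125	-1.65	0.002	0.998	5.78
rs373000659	NUP155	I553M	missense	snv	0.000092		0			probably-damaging	0.985	10	-2.83	0.013	0.988	-1.05
rs202194194	NUP155	R1389Q	missense	snv	0.000025		0			probably-damaging	0.987	43	-5.81	0.141	1	5.05
rs148457088	NUP155	P497L	missense	snv	0.00002		0			probably-damaging	0.989	98	-4.15	0.112	1	5.41
rs376772699	NUP155	G155D	missense	snv	0.000004		0			probably-damaging	0.993	94	-4.91	0.005	0.993	4.85
rs142350078	NUP155	S337F	missense	snv	0.000046		0			probably-damaging	0.994	155	-2.55	0.061	1	5.46
rs368777239	NUP155	F727C	missense	snv	0.000008		0			probably-damaging	0.995	205	-1.91	0.176	0.999	5.78
rs151163391	NUP155	K1253N	missense	snv	0.000004		0			probably-damaging	0.996	94	-1.46	0.496	0.971	0.43
rs145147317	NUP155	G754R	missense	snv	0.000032		0			probably-damaging	0.997	125	-6.36	0.002	1	4.49
rs375239602	NUP155	P516L	missense	snv	0.000014		0			probably-damaging	0.997	98	-1.27	0.253	1	5.55
rs143375056	NUP155	S371N	missense	snv	0.000004		0			probably-damaging	0.998	46	-5.97	0.007	1	3.64
rs370781964	NUP155	P209L	missense	snv	0.000008		0			probably-damaging	0.998	98	-5.97	0.007	1	5.83
rs149244067	NUP155	L947F	missense	snv	0.000004		0			probably-damaging	0.999	22	-2.61	0	0.995	4.59
rs145975462	NUP155	L866V	missense	snv	0.000039		0			probably-damaging	0.999	32	-6.5	0.002	1	6.16
rs142961329	NUP155	D848H	missense	snv	0.000032		0			probably-damaging	0.999	81	-6.27	0.001	1	5.85
rs141688173	NUP155	D429V	missense	snv	0.000591		0			probably-damaging	0.999	152	-3.08	0.009	1	5.07
rs376696300	NUP155	R336H	missense	snv	0.000056		0			probably-damaging	1.0	29	-1.99	0.024	1	5.46
rs202058711	NUP155	R750H	missense	snv	0.000139		0			probably-damaging	1.0	29	-6.5	0	1	5.59
rs373119361	NUP155	R1120Q	missense	snv	0.000008		0			probably-damaging	1.0	43	-4.43	0.001	1	5.44
rs145640004	NUP155	A1204G	missense	snv	0.000012		0			probably-damaging	1.0	60	-3.59	0	1	5.11
rs376271013	NUP155	P990H	missense	snv	0.000004		0			probably-damaging	1.0	77	-1.27	0.017	1	4.8
rs373376199	NUP155	R672G	missense	snv	0.000007		0			probably-damaging	1.0	125	-6.5	0.024	1	5.16
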