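individual	code	sex	age_class	age_years	group	hours_observed	n_sessions	n_pf	n_fpf
Yaounde	YA	M	Ad	37	VDS	92	9	6	14
Hakuna	HA	F	Ad	24	VDS	80.5	24	7	3
Virunga	VI	F	Ad	50	VDS	78	2	1	0
Moseka	MO	F	Ad	35	VDS	71.5	0	0	0
Mahmah	MA	F	Ad	18	VDS	79	85	48	53
Mawete	MW	M	SubAd	9	VDS	62.5	209	70	209
Djomo	DJ	M	SubAd	12	VDS	63	43	15	50
Kouam	KO	M	Inf	4	VDS	63	281	70	207
Ivindo	IV	F	Inf	3	VDS	70	190	32	114
Basoko	BA	M	Inf	0	VDS	75	86	49	112
Asato	AS	M	Ad	30	BEA	43.5	0	0	0
Kabinda	KA	F	Ad	39	BEA	42	0	0	0
Inge	IN	F	Ad	41	BEA	43	2	1	0
Sheila	SH	F	Ad	30	BEA	42	0	0	0
Mapenzi	MP	M	SubAd	11	BEA	41	8	1	2
Sawa	SA	F	SubAd	10	BEA	42	3	0	0
Mayele	MY	F	SubAd	8	BEA	41.5	2	1	1
Yamba	YB	M	SubAd	6	BEA	42.5	18	2	10
Kivano	KI	M	SubAd	5	BEA	42	13	1	2
Mbaku	MB	M	Inf	3	BEA	43	28	7	35
Kovanga	KV	M	Inf	2	BEA	42.5	23	6	19
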