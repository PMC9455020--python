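region	crane	sex	haplotype	Id-01	Id-02	Id-03	Id-04	Id-05	Id-06	Id-07	Id-08	Id-9	Id-10	Id-11
Kushiro	70	Female	Gj2	W Homo	D Homo	WI Hetero	W Homo	W Homo	WD Hetero	D Homo	W Homo	W Homo	W Homo	W Homo
Kushiro	89	Female	Gj1	W Homo	W Homo	WI Hetero	W Homo	WD Hetero	WD Hetero	WD Hetero	W Homo	W Homo	WD Hetero	W Homo
Kushiro	123	Male	Gj1	W Homo	W Homo	W Homo	W Homo	WD Hetero	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo
Kushiro	150	Male	Gj2	W Homo	WD Hetero	I Homo	W Homo	WD Hetero	W Homo	WD Hetero	WD Hetero	W Homo	WD Hetero	W Homo
Kushiro	194	Female	Gj1	W Homo	W Homo	W Homo	W Homo	WD Hetero	W Homo	D Homo	W Homo	W Homo	W Homo	W Homo
Kushiro	211	Male	Gj2	W Homo	W Homo	W Homo	W Homo	W Homo	WD Hetero	W Homo	WD Hetero	W Homo	W Homo	W Homo
Kushiro	247	Male	Gj2	W Homo	D Homo	W Homo	W Homo	W Homo	W Homo	WD Hetero	WD Hetero	W Homo	WD Hetero	W Homo
Kushiro	251	Female	Gj2	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo	WD Hetero	W Homo	W Homo	W Homo	W Homo
Kushiro	271	Male	Gj2	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo	WD Hetero	WD Hetero	W Homo	W Homo
Kushiro	315	Female	Gj2	WD Hetero	WD Hetero	I Homo	WD Hetero	WD Hetero	W Homo	D Homo	W Homo	WD Hetero	W Homo	WD Hetero
Kushiro	344	Male	Gj2	W Homo	W Homo	WI Hetero	W Homo	W Homo	WD Hetero	W Homo	WD Hetero	WD Hetero	WD Hetero	W Homo
Kushiro	361	Male	Gj2	W Homo	D Homo	W Homo	W Homo	W Homo	WD Hetero	WD Hetero	W Homo	W Homo	W Homo	W Homo
Kushiro	362	Male	Gj1	W Homo	W Homo	WI Hetero	W Homo	W Homo	D Homo	W Homo	WD Hetero	W Homo	WD Hetero	W Homo
Nemuro	54	Male	Gj2	W Homo	W Homo	WI Hetero	W Homo	W Homo	WD Hetero	WD Hetero	WD Hetero	W Homo	WD Hetero	W Homo
Nemuro	72	Female	Gj2	W Homo	W Homo	WI Hetero	W Homo	WD Hetero	W Homo	WD Hetero	W Homo	W Homo	WD Hetero	W Homo
Nemuro	127	Male	Gj2	W Homo	W Homo	WI Hetero	W Homo	WD Hetero	WD Hetero	WD Hetero	W Homo	W Homo	WD Hetero	W Homo
Nemuro	137	Male	Gj2	W Homo	W Homo	WI Hetero	W Homo	W Homo	WD Hetero	WD Hetero	WD Hetero	W Homo	D Homo	W Homo
Nemuro	139	Female	Gj2	W Homo	W Homo	W Homo	W Homo	W Homo	WD Hetero	W Homo	W Homo	W Homo	W Homo	W Homo
Nemuro	223	Male	Gj2	WD Hetero	WD Hetero	W Homo	WD Hetero	W Homo	WD Hetero	WD Hetero	WD Hetero	W Homo	D Homo	W Homo
Nemuro	280	Female	Gj2	W Homo	WD Hetero	W Homo	WD Hetero	W Homo	W Homo	W Homo	W Homo	W Homo	WD Hetero	W Homo
Nemuro	287	Female	Gj2	WD Hetero	W Homo	W Homo	W Homo	WD Hetero	W Homo	WD Hetero	W Homo	W Homo	D Homo	W Homo
Nemuro	319	Male	Gj2	W Homo	WD Hetero	W Homo	WD Hetero	WD Hetero	W Homo	W Homo	W Homo	W Homo	D Homo	W Homo
Nemuro	330	Female	Gj2	W Homo	D Homo	I Homo	W Homo	W Homo	WD Hetero	D Homo	D Homo	W Homo	W Homo	W Homo
Nemuro	331	Female	Gj2	W Homo	WD Hetero	I Homo	W Homo	W Homo	WD Hetero	W Homo	W Homo	W Homo	W Homo	W Homo
Nemuro	396	Female	Gj2	W Homo	WD Hetero	I Homo	W Homo	WD Hetero	WD Hetero	W Homo	D Homo	W Homo	D Homo	W Homo
Nemuro	397	Female	Gj2	W Homo	W Homo	W Homo	W Homo	W Homo	D Homo	WD Hetero	W Homo	W Homo	W Homo	W Homo
Tokachi	63	Female	Gj2	W Homo	WD Hetero	W Homo	WD Hetero	W Homo	W Homo	WD Hetero	W Homo	W Homo	WD Hetero	W Homo
Tokachi	71	Female	Gj2	W Homo	D Homo	I Homo	W Homo	WD Hetero	W Homo	WD Hetero	W Homo	W Homo	W Homo	W Homo
Tokachi	78	Male	Gj2	W Homo	W Homo	WI Hetero	W Homo	W Homo	W Homo	WD Hetero	W Homo	W Homo	W Homo	D Homo
Tokachi	109	Female	Gj2	W Homo	WD Hetero	W Homo	W Homo	WD Hetero	W Homo	WD Hetero	W Homo	WD Hetero	WD Hetero	W Homo
Tokachi	131	Female	Gj2	WD Hetero	WD Hetero	I Homo	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo
Tokachi	187	Male	Gj2	W Homo	W Homo	WI Hetero	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo
Tokachi	201	Male	Gj2	WD Hetero	D Homo	W Homo	W Homo	W Homo	WD Hetero	W Homo	W Homo	WD Hetero	WD Hetero	W Homo
Tokachi	207	Male	Gj2	W Homo	WD Hetero	I Homo	W Homo	WD Hetero	WD Hetero	W Homo	W Homo	W Homo	WD Heter	W Homo
Tokachi	213	Female	Gj2	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo	WD Hetero	W Homo	W Homo	WD Heter	W Homo
Tokachi	254	Female	Gj2	WD Hetero	WD Hetero	W Homo	W Homo	WD Hetero	W Homo	W Homo	D Homo	WD Hetero	W Homo	WD Hetero
Tokachi	256	Female	Gj2	W Homo	W Homo	WI Hetero	W Homo	W Homo	W Homo	W Homo	D Homo	W Homo	W Homo	WD Hetero
Tokachi	371	Male	Gj1	WD Hetero	WD Hetero	W Homo	W Homo	WD Hetero	W Homo	W Homo	W Homo	WD Hetero	WD Heter	W Homo
Tokachi	373	Female	Gj1	WD Hetero	W Homo	W Homo	W Homo	W Homo	WD Hetero	WD Hetero	W Homo	WD Hetero	WD Heter	W Homo
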