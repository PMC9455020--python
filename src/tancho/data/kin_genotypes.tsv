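crane	relationship	sex	haplotype	family	Id-01	Id-02	Id-03	Id-04	Id-05	Id-06	Id-07	Id-08	Id-9	Id-10	Id-11
207	Father	Male	Gj2	F01	W Homo	WD Hetero	I Homo	W Homo	WD Hetero	WD Hetero	W Homo	W Homo	W Homo	WD Hetero	W Homo
352	Sibling of 207	Male	Gj2	F01	W Homo	WD Hetero	I Homo	W Homo	WD Hetero	WD Hetero	W Homo	W Homo	W Homo	W Homo	W Homo
387	Sibling of 207	Female	Gj2	F01	W Homo	W Homo	I Homo	W Homo	WD Hetero	W Homo	W Homo	W Homo	W Homo	WD Hetero	WD Hetero
388	Sibling of 207	Female	Gj2	F01	W Homo	WD Hetero	I Homo	W Homo	W Homo	WD Hetero	W Homo	W Homo	W Homo	W Homo	W Homo
213	Mother	Female	Gj2	F02	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo	WD Hetero	W Homo	W Homo	WD Hetero	W Homo
374	Sibling of 213	Female	Gj2	F02	W Homo	W Homo	W Homo	W Homo	WD Hetero	W Homo	W Homo	W Homo	W Homo	WD Hetero	W Homo
T73/R568	Father of 116-390	Male	Gj2	F03	W Homo	WD Hetero	WI Hetero	W Homo	WD Hetero	W Homo	WD Hetero	WD Hetero	W Homo	W Homo	W Homo
116	Mother of 358, 359	Female	Gj2	F03	WD Hetero	W Homo	W Homo	W Homo	D Homo	W Homo	W Homo	D Homo	W Homo	WD Hetero	WD Hetero
204	Sibling of T73	Female	Gj2	F03	WD Hetero	WD Hetero	I Homo	W Homo	W Homo	W Homo	WD Hetero	W Homo	W Homo	W Homo	WD Hetero
261	Sibling of T73	Female	Gj2	F03	WD Hetero	W Homo	W Homo	W Homo	WD Hetero	W Homo	WD Hetero	D Homo	W Homo	W Homo	W Homo
312	Sibling of T73	Female	Gj2	F03	WD Hetero	W Homo	W Homo	W Homo	WD Hetero	W Homo	WD Hetero	D Homo	W Homo	WD Hetero	WD Hetero
313	Sibling of T73	Female	Gj2	F03	WD Hetero	WD Hetero	W Homo	W Homo	WD Hetero	W Homo	WD Hetero	W Homo	W Homo	W Homo	W Homo
353	Sibling of T73	Male	Gj2	F03	WD Hetero	WD Hetero	I Homo	W Homo	WD Hetero	W Homo	WD Hetero	WD Hetero	W Homo	W Homo	W Homo
390	Sibling of T73	Female	Gj2	F03	WD Hetero	WD Hetero	W Homo	W Homo	D Homo	W Homo	W Homo	D Homo	W Homo	WD Hetero	W Homo
253	Grandsibling of T73	Male	Gj2	F03	WD Hetero	W Homo	WI Hetero	W Homo	WD Hetero	W Homo	D Homo	WD Hetero	W Homo	W Hetero	W Homo
384	Grandsibling of T73	Female	Gj2	F03	WD Hetero	W Homo	W Homo	W Homo	WD Hetero	W Homo	D Homo	W Homo	W Homo	W Hetero	W Homo
358	Grandsibling of T73	Male	Gj2	F03	W Homo	W Homo	W Homo	W Homo	WD Hetero	W Homo	W Homo	WD Hetero	W Homo	WD Hetero	WD Hetero
359	Grandsibling of T73	Female	Gj2	F03	W Homo	W Homo	W Homo	W Homo	WD Hetero	W Homo	W Homo	W Homo	W Homo	WD Hetero	WD Hetero
123	Father	Male	Gj1	F04	W Homo	W Homo	W Homo	W Homo	WD Hetero	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo
131	Mother	Female	Gj2	F04	WD Hetero	WD Hetero	I Homo	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo
244	Sibling of 123 and 131	Male	Gj2	F04	W Homo	W Homo	WI Hetero	W Homo	WD Hetero	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo
245	Twins of 244	Female	Gj2	F04	W Homo	WD Hetero	W Homo	W Homo	WD Hetero	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo
211	Father	Male	Gj2	F05	W Homo	W Homo	W Homo	W Homo	W Homo	WD Hetero	W Homo	WD Hetero	W Homo	W Homo	W Homo
362	Sibling of 211	Male	Gj1	F05	W Homo	W Homo	WI Hetero	W Homo	W Homo	D Homo	W Homo	WD Hetero	W Homo	WD Hetero	W Homo
315	Twins of 316	Female	Gj2	F06	WD Hetero	WD Hetero	I Homo	WD Hetero	WD Hetero	W Homo	D Homo	W Homo	WD Hetero	W Homo	WD Hetero
316	Twins of 315	Male	Gj2	F06	W Homo	W Homo	WI Hetero	WD Hetero	W Homo	W Homo	WD Hetero	WD Hetero	W Homo	W Homo	WD Hetero
201	Father	Male	Gj2	F07	WD Hetero	D Homo	W Homo	W Homo	W Homo	WD Hetero	W Homo	W Homo	WD Hetero	WD Hetero	W Homo
375	Sibling of 201	Female	Gj2	F07	W Homo	WD Hetero	W Homo	W Homo	W Homo	WD Hetero	W Homo	W Homo	W Homo	WD Hetero	W Homo
63	Mother	Female	Gj2	F08	W Homo	WD Hetero	W Homo	WD Hetero	W Homo	W Homo	WD Hetero	W Homo	W Homo	WD Hetero	W Homo
169	Sibling of 63	Male	Gj2	F08	W Homo	WD Hetero	W Homo	W Homo	W Homo	WD Hetero	WD Hetero	W Homo	WD Hetero	WD Hetero	W Homo
109	Mother	Female	Gj2	F09	W Homo	WD Hetero	W Homo	W Homo	WD Hetero	W Homo	WD Hetero	W Homo	WD Hetero	WD Hetero	W Homo
392	Sibling of 109	Female	Gj2	F09	W Homo	WD Hetero	I Homo	W Homo	D Homo	WD Hetero	WD Hetero	W Homo	W Homo	W Homo	W Homo
T74/R566	Father	Male	-	F10	WD Hetero	WD Hetero	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo	WD Hetero	WD Hetero	W Homo
124	Sibling of T74	Female	Gj1	F10	W Homo	D Homo	W Homo	W Homo	WD Hetero	W Homo	W Homo	W Homo	W Homo	WD Hetero	W Homo
125	Sibling of T74	Male	Gj1	F10	WD Hetero	WD Hetero	W Homo	W Homo	WD Hetero	W Homo	W Homo	W Homo	WD Hetero	W Homo	W Homo
251	Mother	Female	Gj2	F11	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo	WD Hetero	W Homo	W Homo	W Homo	W Homo
415	Sibling of 251	Male	Gj2	F11	W Homo	W Homo	WI Hetero	W Homo	WD Hetero	WD Hetero	WD Hetero	W Homo	WD Hetero	W Homo	W Homo
271	Father	Male	Gj2	F12	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo	WD Hetero	WD Hetero	W Homo	W Homo
420	Sibling of 271	Female	Gj1	F12	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo	W Homo	WD Hetero	W Homo	W Homo
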