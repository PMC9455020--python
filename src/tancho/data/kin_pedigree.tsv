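relation	id1	id2
parent_offspring	207	352
parent_offspring	207	387
parent_offspring	207	388
parent_offspring	213	374
parent_offspring	T73/R568	116
parent_offspring	T73/R568	204
parent_offspring	T73/R568	261
parent_offspring	T73/R568	312
parent_offspring	T73/R568	313
parent_offspring	T73/R568	353
parent_offspring	T73/R568	390
parent_offspring	116	358
parent_offspring	116	359
parent_offspring	123	244
parent_offspring	123	245
parent_offspring	131	244
parent_offspring	131	245
parent_offspring	211	362
parent_offspring	201	375
parent_offspring	63	169
parent_offspring	109	392
parent_offspring	T74/R566	124
parent_offspring	T74/R566	125
parent_offspring	251	415
parent_offspring	271	420
full_sibling	352	387
full_sibling	352	388
full_sibling	387	388
full_sibling	116	204
full_sibling	116	261
full_sibling	116	312
full_sibling	116	313
full_sibling	116	353
full_sibling	116	390
full_sibling	204	261
full_sibling	204	312
full_sibling	204	313
full_sibling	204	353
full_sibling	204	390
full_sibling	261	312
full_sibling	261	313
full_sibling	261	353
full_sibling	261	390
full_sibling	312	313
full_sibling	312	353
full_sibling	312	390
full_sibling	313	353
full_sibling	313	390
full_sibling	353	390
full_sibling	358	359
full_sibling	244	245
full_sibling	124	125
full_sibling	253	384
twin	244	245
twin	315	316
grandparent	T73/R568	253
grandparent	T73/R568	384
grandparent	T73/R568	358
grandparent	T73/R568	359
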