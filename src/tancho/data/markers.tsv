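marker_id	chromosome	span_start	span_end	variant_type	indel_size	product_bp	forward_primer	reverse_primer
Id-01	Grja_16152	2703	2734	deletion	32	200	AATTCAGTGGGTTTGCTCCCGCGGAA	TCAGTTCGTGTCGTACGTTGTCCCA
Id-02	Grja_24077	3699	3730	deletion	32	205	AGCAGCTCTGGAGTCACCAAAGCA	TCAAAATGGTTCCATGTGCCCTGTGT
Id-03	Grja_10155	1061	1090	insertion	30	160	GCAGGATAGCAGCCTAATTGTATCAA	AGGTAGGGCAACTTTAAAGTACTTTGA
Id-04	Grja_25718	20476	20505	deletion	30	234	AAAGGAGGGAATTTGCAGAGCCCA	TGTGTTTTCTGAGACTTTCCACTCT
Id-05	Grja_8974	39698	39727	deletion	30	207	TGGTATGTCTGCCACTCAGAAAGGGA	AGAAACAGGTAAAGGCTCACACCAGA
Id-06	Grja_3909	47326	47361	deletion	36	147	TGACTACCTGTGCACCCAGACAGCA	ATGGTGTGGTGGCATGCCAGCAAATA
Id-07	Grja_36880	1992	2021	deletion	30	175	ATGTCTCTCTTGTGTCCCCTTGGGA	ACAGCCCAGAGATGGTGGCCACAA
Id-08	Grja_29257	18954	18984	deletion	31	236	TAGCAAAGCTCCAGAACAGGACTCCT	AGAGTTTCAGTACAGAAAGACCTGCT
Id-9	Grja_13764	9525	9554	deletion	30	251	TATGGTAACGGAACAGGGAGGGGGT	TGTCCCTTGTTTCAGTTCCAGCAGCT
Id-10	Grja_2883	30876	30905	deletion	30	183	ACATGTTGGCCTTTAAAGGCTGAGCA	AGGAGCACCGACTAGCATTCAGCAT
Id-11	Grja_3871	53311	53340	deletion	30	180	ACCTCACTACTAGCTCCTTATTCA	TTAGATAAGCCTGCCTCTGTAACTA
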