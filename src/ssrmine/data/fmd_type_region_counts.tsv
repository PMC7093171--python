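# Published per-repeat-type perfect SSR locus counts for the forest musk deer
# genome: genome-wide and per genomic region (5'UTR, CDS, intron, 3'UTR,
# TE overlay, intergenic).  Totals are NOT included; they are recomputed.
region	unit_length	n_loci
genome	1	273518
genome	2	148175
genome	3	122105
genome	4	39977
genome	5	96262
genome	6	598
5'UTR	1	115
5'UTR	2	60
5'UTR	3	178
5'UTR	4	38
5'UTR	5	9
5'UTR	6	5
CDS	1	26
CDS	2	16
CDS	3	2419
CDS	4	23
CDS	5	18
CDS	6	86
intron	1	72591
intron	2	45758
intron	3	36275
intron	4	13458
intron	5	32870
intron	6	173
3'UTR	1	598
3'UTR	2	316
3'UTR	3	83
3'UTR	4	56
3'UTR	5	19
3'UTR	6	2
TE	1	58987
TE	2	27997
TE	3	6789
TE	4	12619
TE	5	3683
TE	6	74
intergenic	1	135726
intergenic	2	89153
intergenic	3	53607
intergenic	4	28975
intergenic	5	50814
intergenic	6	791
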