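# Published diversity statistics for the tetranucleotide SSR marker panel
# genotyped in 36 captive forest musk deer (Moschus berezovskii).
# 21 retained loci plus the HWE-deviant locus LS-55-1 (P < 0.01, retained=False;
# only its allele count and allelic richness were reported).
# Columns: locus, repeat unit as printed, N individuals typed, allele count k,
# observed/expected heterozygosity, allelic richness, PIC, HWE exact P, retained.
locus	repeat_unit	n	k	ho	he	ar	pic	hwe_p	retained
LS-2-1	(GCAG)10	36	6	0.385	0.65	6.000	0.593	0.03	True
LS-6-1	(GATG)8	36	3	0.538	0.555	3.000	0.484	0.376	True
LS-7-1	(AGGA)8	36	2	0.154	0.145	2.000	0.132	0.884	True
LS-8-1	(AGAC)8	36	5	0.654	0.675	5.000	0.598	0.311	True
LS-9-1	(ATAG)8	36	3	0.192	0.278	2.895	0.255	0.054	True
LS-12-3	(CAGA)8	36	3	0.538	0.679	3.00	0.592	0.097	True
LS-13-1	(AGAA)8	36	6	0.615	0.655	6.000	0.582	0.253	True
LS-14-2	(TGCG)8	36	6	0.692	0.735	5.997	0.683	0.562	True
LS-16-1	(AGAC)8	36	4	0.577	0.508	3.990	0.454	0.181	True
LS-17-1	(TATG)8	36	4	0.615	0.63	4.000	0.548	0.503	True
LS-18-1	(CCAT)8	36	3	0.577	0.562	2.993	0.472	0.391	True
LS-24-1	(TTGG)7	36	4	0.615	0.613	4.000	0.555	0.607	True
LS-27-1	(ATGG)7	36	4	0.308	0.278	3.995	0.257	0.54	True
LS-28-1	(ATCC)7	36	3	0.154	0.147	3.000	0.138	0.883	True
LS-29-1	(TTTA)7	36	3	0.346	0.386	3.000	0.343	0.351	True
LS-30-1	(ATCC)7	36	2	0.231	0.208	1.968	0.183	0.722	True
LS-31-1	(ATGG)7	36	2	0.154	0.208	2.000	0.183	0.274	True
LS-35-1	(TGGA)7	36	2	0.115	0.111	1.965	0.103	0.94	True
LS-47-1	(CCAA)15	36	4	0.615	0.571	4.000	0.512	0.319	True
LS-50-1	(TCCA)12	36	4	0.5	0.455	3.995	0.397	0.235	True
LS-56-1	(CATA)12	36	3	0.308	0.305	3.000	0.277	0.656	True
LS-55-1	(CATA)14	36	7	NA	NA	7.00	NA	NA	False
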