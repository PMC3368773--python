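gene	amino_acid	aln_length	identical	pct_inuc
trnA	Alanine	72	21	29.17
trnC	Cysteine	66	39	59.09
trnD	Aspartate	66	26	39.39
trnE	Glutamate	65	27	41.54
trnF	Phenylalanine	68	22	32.35
trnG	Glycine	67	39	58.21
trnH	Histidine	67	25	37.31
trnI	Isoleucine	72	28	38.89
trnK	Lysine	73	23	31.51
trnL1	Leucine_CUN	69	21	30.43
trnL2	Leucine_UUR	68	28	41.18
trnM	Methionine	66	38	57.58
trnN	Asparagine	69	20	28.99
trnP	Proline	67	24	35.82
trnQ	Glutamine	70	28	40.00
trnR	Arginine	67	16	23.88
trnS1	Serine_UCN	71	23	32.39
trnS2	Serine_AGN	73	30	41.10
trnT	Threonine	71	23	32.39
trnV	Valine	69	33	47.83
trnW	Tryptophan	70	27	38.57
trnY	Tyrosine	68	32	47.06
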