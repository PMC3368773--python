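species	total_nt	pct_T	pct_C	pct_A	pct_G	pct_AT	at_skew	gc_skew
Cephalothrix_hongkongiensis	16296	47.4	10.2	27.5	14.9	74.9	-0.266	0.187
Cephalothrix_sp	15800	47.9	10.0	27.8	14.3	75.7	-0.266	0.178
Paranemertes_cf_peregrina	14558	47.5	10.0	22.8	19.7	70.3	-0.351	0.322
Nectonemertes_cf_mirabilis	15365	48.5	10.5	21.8	19.2	70.3	-0.380	0.293
Lineus_viridis	15388	44.4	11.9	21.3	22.4	65.7	-0.352	0.306
Zygeupolia_rubens	15513	45.0	9.8	21.0	24.2	66.0	-0.364	0.424
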