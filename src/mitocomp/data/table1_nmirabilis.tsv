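#genome_id=Nectonemertes_cf_mirabilis
#length=15365
#circular=true
name	span	class	size_printed	spacer_printed
trnY	1-62	tRNA	62	0
trnP	125-63	tRNA	63	2
nad6	128-583	protein	456	21
cob	605-1741	protein	1137	9
trnS1	1751-1811	tRNA	61	-1
trnT	1876-1811	tRNA	66	2
nad4L	1879-2181	protein	303	-7
nad4	2175-3536	protein	1362	6
trnH	3543-3602	tRNA	60	0
nad5	3603-5348	protein	1746	-1
trnE	5348-5410	tRNA	63	1
trnG	5412-5474	tRNA	63	2
cox3	5477-6256	protein	780	9
trnK	6266-6332	tRNA	67	-2
trnA	6331-6393	tRNA	63	5
trnF	6399-6464	tRNA	66	1
trnQ	6466-6532	tRNA	67	0
trnR	6533-6598	tRNA	66	1
trnN	6600-6662	tRNA	63	2
trnI	6665-6730	tRNA	66	1
nad3	6732-7085	protein	354	5
cox1	7091-8626	protein	1536	12
trnW	8639-8703	tRNA	65	0
AT-rich	8704-9405	noncoding	702	0
trnS2	9406-9473	tRNA	68	-1
nad2	9473-10480	protein	1008	5
cox2	10486-11166	protein	681	14
trnD	11181-11245	tRNA	65	0
atp8	11246-11402	protein	157	40
atp6	11443-12132	protein	700	5
trnC	12138-12198	tRNA	61	0
trnM	12199-12263	tRNA	65	0
rrnS	12264-13068	rRNA	805	0
trnV	13069-13130	tRNA	62	0
rrnL	13131-14308	rRNA	1178	0
trnL1	14309-14372	tRNA	64	1
trnL2	14374-14435	tRNA	62	2
nad1	14438-15361	protein	924	4
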