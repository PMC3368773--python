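#genome_id=Zygeupolia_rubens
#length=15513
#circular=true
name	span	class	size_printed	spacer_printed
trnY	1-64	tRNA	64	0
trnP	131-65	tRNA	67	3
nad6	135-599	protein	465	-8
cob	592-1728	protein	1137	-1
trnS1	1728-1798	tRNA	71	-1
trnT	1861-1798	tRNA	64	2
nad4L	1864-2169	protein	306	-7
nad4	2163-3509	protein	1347	1
trnH	3511-3574	tRNA	64	2
nad5	3577-5308	protein	1732	0
trnE	5309-5372	tRNA	64	1
trnG	5374-5438	tRNA	65	2
cox3	5441-6220	protein	780	6
trnK	6227-6287	tRNA	61	-1
trnA	6287-6350	tRNA	64	0
trnF	6351-6415	tRNA	65	0
trnQ	6416-6484	tRNA	69	0
trnR	6485-6550	tRNA	66	1
trnN	6552-6616	tRNA	65	0
trnI	6617-6681	tRNA	65	1
nad3	6683-7039	protein	357	0
AT-rich	7040-7877	noncoding	838	0
trnS2	7878-7949	tRNA	72	0
nad2	7950-8957	protein	1008	3
cox1	8961-10493	protein	1533	0
trnW	10494-10558	tRNA	65	3
cox2	10562-11246	protein	685	0
trnD	11247-11312	tRNA	66	0
atp8	11313-11471	protein	159	5
atp6	11477-12169	protein	693	1
trnC	12171-12232	tRNA	62	0
trnM	12233-12296	tRNA	64	0
rrnS	12297-13132	rRNA	836	0
trnV	13133-13200	tRNA	68	0
rrnL	13201-14448	rRNA	1248	0
trnL1	14449-14515	tRNA	67	0
trnL2	14516-14582	tRNA	67	0
nad1	14583-15513	protein	931	0
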