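# Signed circular mitochondrial gene orders (minus = L strand).
# The two nemertean orders are derived from the annotation coordinates; the
# bilaterian ground pattern is a reconstruction of the classic ancestral
# (human-like) arrangement used as the comparison baseline.
Nectonemertes_cf_mirabilis: trnY -trnP nad6 cob trnS1 -trnT nad4L nad4 trnH nad5 trnE trnG cox3 trnK trnA trnF trnQ trnR trnN trnI nad3 cox1 trnW trnS2 nad2 cox2 trnD atp8 atp6 trnC trnM rrnS trnV rrnL trnL1 trnL2 nad1
Zygeupolia_rubens: trnY -trnP nad6 cob trnS1 -trnT nad4L nad4 trnH nad5 trnE trnG cox3 trnK trnA trnF trnQ trnR trnN trnI nad3 trnS2 nad2 cox1 trnW cox2 trnD atp8 atp6 trnC trnM rrnS trnV rrnL trnL1 trnL2 nad1
bilaterian_ground_pattern: trnF rrnS trnV rrnL trnL2 nad1 trnI -trnQ trnM nad2 trnW -trnA -trnN -trnC -trnY cox1 -trnS1 trnD cox2 trnK atp8 atp6 cox3 trnG nad3 trnR nad4L nad4 trnH trnS2 trnL1 nad5 -nad6 -trnE cob trnT -trnP
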