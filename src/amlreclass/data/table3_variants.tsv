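# Mutations located inside the CN-LOH regions above, with published VAFs (percent).
# Footnoted mutations are included: the AQ5327 ASXL2 VAF is a synthetic stand-in
# (published only as "< 50%", encoded 45); the AQ5344 second WT1 mutation is at 12%.
# KMT2A-PTD rows carry no VAF (blank), as published.
patient_id	gene	hgvs_c	hgvs_p	variant_class	impact	alt_reads	vaf_pct	oncogenicity	paired_normal
AQ5342	DNMT3A	c.1742G>A	p.Trp581Ter	SNV	HIGH	60	71	ONCOGENIC	true
AQ5327	DNMT3A	c.1813del	p.Leu605SerfsTer46	indel	HIGH	60	97	ONCOGENIC	true
AQ5327	ASXL2	c.2444del	p.Pro815fs	indel	HIGH	40	45	LIKELY_ONCOGENIC	true
AQ5357	EZH2	c.203_204del	p.Val68AlafsTer13	indel	HIGH	55	85	ONCOGENIC	true
AQ5390	CUX1	c.634C>T	p.Gln212Ter	SNV	HIGH	70	98	ONCOGENIC	true
AQ5359	WT1	c.1152dup	p.Arg385ThrfsTer5	indel	HIGH	50	79	ONCOGENIC	true
AQ5344	WT1	c.1264+1G>C		SNV	HIGH	48	73	ONCOGENIC	true
AQ5344	WT1	c.812dup	p.Val272GlyfsTer26	indel	HIGH	12	12	LIKELY_ONCOGENIC	true
AQ5340	KMT2A			KMT2A_PTD	HIGH	30		LIKELY_ONCOGENIC	true
AQ5383	CBL	c.1228-1G>A		SNV	HIGH	58	88	ONCOGENIC	true
AQ5389	KMT2A			KMT2A_PTD	HIGH	30		LIKELY_ONCOGENIC	true
AQ5351	NF1	c.4577+2T>G		SNV	HIGH	52	86	ONCOGENIC	true
AQ5335	RUNX1	c.592G>T	p.Asp198Tyr	SNV	MODERATE	25	29	ONCOGENIC	true
AQ5333	RUNX1	c.496C>T	p.Arg166Ter	SNV	HIGH	62	89	ONCOGENIC	true
AQ5336	RUNX1	c.637C>T	p.Gln213Ter	SNV	HIGH	54	78	ONCOGENIC	true
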