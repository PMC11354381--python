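# Machine-readable CN-LOH segment table (45 evaluated patients; GRCh38, 1-based closed).
# The AQ5368 row is stored with its two published positions sorted (the printed start
# exceeded the printed end). The final AQ5331 row encodes the footnoted homozygous
# copy loss at the RUNX1 locus as a LOSS segment (0,0); its coordinates are the
# RUNX1 gene interval (synthetic stand-in, not printed in the source table).
patient_id	chrom	start_bp	end_bp	n_major	n_minor
AQ5342	chr2	41404	85325063	2	0
AQ5327	chr2	41404	27616502	2	0
AQ5366	chr6	166931095	170583760	2	0
AQ5357	chr7	63096280	159232490	2	0
AQ5390	chr7	70768153	159232490	2	0
AQ5368	chr11	43554371	43754184	2	0
AQ5359	chr11	199813	45812493	2	0
AQ5344	chr11	199813	35968505	2	0
AQ5340	chr11	66551501	134857757	2	0
AQ5380	chr3	319825	81648979	2	0
AQ5383	chr11	57688772	134857757	2	0
AQ5389	chr11	65999744	134857757	2	0
AQ5351	chr17	27280695	83054873	2	0
AQ5395	chr17	161952	21016024	2	0
AQ5335	chr21	13384722	46608083	2	0
AQ5363	chr21	13384722	46608083	2	0
AQ5331	chr21	29591425	46608083	2	0
AQ5333	chr21	32268841	46608083	2	0
AQ5336	chr21	32319444	46618727	2	0
AQ5351	chr22	16136750	50740572	2	0
AQ5331	chr21	34787801	35049344	0	0
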