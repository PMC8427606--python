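# Published SMR-HEIDI results for the 13 significant miRNA-cancer associations
# in hormone-dependent cancers (FDR(SMR) < 0.05 and P(HEIDI) > 0.01).
cancer	chr	bp	top_snp	mirna	b_smr	se_smr	fdr_smr	p_heidi
Prostate	8	92060665	rs6999873	hsa-miR-4661-5p	-0.0898	0.0377	0.0174	0.2017
Prostate	9	73282815	rs10124022	hsa-miR-204-5p	-0.0517	0.0252	0.0401	0.8918
Breast	12	54420098	rs4759318	hsa-miR-196a-3p	-0.0578	0.0221	0.0088	0.3310
Breast	2	190013146	rs9288163	hsa-miR-3129-3p	-0.1011	0.0355	0.0044	0.1789
Breast	5	148441321	rs36047	hsa-miR-584-5p	-0.1713	0.0564	0.0024	0.5121
Breast ER-	3	195750742	rs9820939	hsa-miR-570-3p	-0.2441	0.0927	0.0085	0.3981
Breast ER+	2	103068156	rs917998	hsa-miR-4772-5p	-0.0606	0.0253	0.0166	0.0547
Endometrial	11	34894166	rs2915232	hsa-miR-1343-3p	0.0779	0.0373	0.0367	0.1240
Endometrial	1	67088603	rs10789211	hsa-miR-3117-3p	0.0949	0.0432	0.0278	0.2559
Endometrial	2	219920412	rs3731881	hsa-miR-3131	-0.0933	0.0385	0.0155	0.0235
Ovarian	8	8346690	rs2976909	hsa-miR-4660	-0.275	0.0987	0.0053	0.3963
Colorectal	2	103066858	rs11465730	hsa-miR-4772-3p	0.1803	0.0809	0.0259	0.3620
Colorectal	2	103034749	rs4851581	hsa-miR-4772-5p	0.0803	0.0414	0.0426	0.2020
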