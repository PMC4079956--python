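detector_id	assay_id	mirna_id	p_value	fc_signed	sequence
mmu-miR-134-4373299	001186	rno-miR-134-5p	0.001	10.83	UGUGACUGGUUGACCAGAGGGG
mmu-miR-342-3p-4395371	002260	rno-miR-342-3p	0.011	4.83	UCUCACACAGAAAUCGCACCCGU
mmu-miR-494-4395476	002365	mmu-miR-494-3p	0.001	4.65	UGAAACAUACACGGGAAACCUC
rno-miR-207-4381096	001315	mmu-miR-207	0.002	3.06	GCUUCUCCUGGCUCUCCUCCCUC
mmu-miR-345-3p-4395659	002529	mmu-miR-345-3p	0.036	3.03	CCUGAACUAGGGGUCUGGAGAC
mmu-miR-193b-4395597	002467	mmu-miR-193b-3p	0.002	2.84	AACUGGCCCACAAAGUCCCGCU
mmu-miR-34a-4395168	000426	rno-miR-34a-5p	0.018	2.74	UGGCAGUGUCUUAGCUGGUUGU
rno-miR-381-4381102	001322	mmu-miR-381-3p	0.047	2.65	UAUACAAGGGCAAGCUCUCUGU
mmu-miR-208-4373091	000511	mmu-miR-208a-3p	0.025	2.57	AUAAGACGAGCAAAAAGCUUGU
mmu-miR-218-4373081	000521	rno-miR-218a-5p	0.028	2.49	UUGUGCUUGAUCUAACCAUGU
mmu-miR-185-4395382	002271	rno-miR-185-5p	0.039	2.44	UGGAGAGAAAGGCAGUUCCUGA
mmu-miR-125b-5p-4373148	000449	rno-miR-125b-5p	0.008	2.08	UCCCUGAGACCCUAACUUGUGA
mmu-miR-140-4373374	001187	rno-miR-140-5p	0.009	1.94	CAGUGGUUUUACCCUAUGGUAG
mmu-miR-16-4373121	000391	rno-miR-16-5p	0.008	1.88	UAGCAGCACGUAAAUAUUGGCG
mmu-miR-489-4378114	001302	mmu-miR-489-3p	0.037	1.78	AAUGACACCACAUAUAUGGCAGC
mmu-miR-208b-4395401	002290	mmu-miR-208b-3p	0.031	1.68	AUAAGACGAACAAAAGGUUUGU
mmu-miR-409-3p-4395443	002332	mmu-miR-409-3p	0.016	1.65	GAAUGUUGCUCGGUGAACCCCU
mmu-miR-320-4395388	002277	rno-miR-320-3p	0.027	1.56	AAAAGCUGGGUUGAGAGGGCGA
mmu-miR-186-4395396	002285	rno-miR-186-5p	0.002	1.5	CAAAGAAUUCUCCUUUUGGGCU
mmu-miR-574-3p-4395460	002349	mmu-miR-574-3p	0.029	1.46	CACGCUCAUGCACACACCCACA
mmu-let-7d-4395394	002283	rno-let-7d-5p	0.002	-1.57	AGAGGUAGUAGGUUGCAUAGUU
mmu-miR-106b-4373155	000442	rno-miR-106b-5p	0.009	-1.65	UAAAGUGCUGACAGUGCAGAU
mmu-miR-363-4378090	001271	mmu-miR-363-3p	0.048	-1.74	AAUUGCACGGUAUCCAUCUGUA
mmu-miR-34b-3p-4395748	002618	rno-miR-34b-3p	0.011	-1.76	AAUCACUAACUCCACUGCCAUC
mmu-miR-23b-4373073	000400	rno-miR-23b-3p	0.001	-2.1	AUCACAUUGCCAGGGAUUACC
mmu-miR-182-4395729	002599	rno-miR-182	0.001	-2.56	UUUGGCAAUGGUAGAACUCACACCG
mmu-miR-30b-4373290	000602	rno-miR-30b-5p	0.023	-2.76	UGUAAACAUCCUACACUCAGCU
mmu-miR-146a-4373132	000468	rno-miR-146a-5p	0.002	-3.21	UGAGAACUGAAUUCCAUGGGUU
mmu-miR-203-4373095	000507	rno-miR-203a-3p	0.037	-3.33	GUGAAAUGUUUAGGACCACUAG
mmu-miR-200c-4395411	002300	mmu-miR-200c-3p	0.000	-3.41	UAAUACUGCCGGGUAAUGAUGGA
mmu-miR-302b-4378071	000531	mmu-miR-302b-3p	0.025	-15.27	UAAGUGCUUCCAUGUUUUAGUAG
mmu-miR-19a-4373099	000395	rno-miR-19a-3p	0.017	-65.54	UGUGCAAAUCUAUGCAAAACUGA
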