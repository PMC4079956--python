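mirna_id	fc_signed	p_value	sequence
rno-miR-378a-3p	3.1775	0.0002	ACUGGACUUGGAGUCAGAAGG
mmu-miR-5100	-23.7	0.001	UCGAAUCCCAGCGGUGCCUCU
rno-miR-30e-3p	3.9961	0.0031	CUUUCAGUCGGAUGUUUACAGC
rno-miR-125b-2-3p	74.135	0.0049	ACAAGUCAGGCUCUUGGGACCU
rno-let-7d-5p	-177.8	0.0084	AGAGGUAGUAGGUUGCAUAGUU
rno-miR-320-5p	92.957	0.01	GCCUUCUCUUCCCGGUUCUUCC
rno-miR-100-5p	10.010	0.012	AACCCGUAGAUCCGAACUUGUG
rno-miR-203a-3p	-5.428	0.0158	GUGAAAUGUUUAGGACCACUAG
rno-miR-21-5p	2.4576	0.0241	UAGCUUAUCAGACUGAUGUUGA
rno-miR-3473	-3.990	0.0308	UCUAGGGCUGGAGAGAUGGCUA
rno-miR-21-3p	14.377	0.0329	CAACAGCAGUCGAUGGGCUGUC
hsa-miR-7641	-3.095	0.0359	UUGAUCUCGGAAGCUAAGC
rno-miR-320-3p	2.7415	0.0394	AAAAGCUGGGUUGAGAGGGCGA
rno-miR-455-5p	44.539	0.0405	UAUGUGCCUUUGGACUACAUCG
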