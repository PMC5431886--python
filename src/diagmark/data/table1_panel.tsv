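# published two-locus assay panel: allele-specific forward pairs with common reverse primers
#assay	role	primer	sequence	product_bp	target_species
153_HH	positive	153_HHp	GATCTGAACATCAGCCACTGC	153	H_huso
153_HH	negative	153_HHn	GATCTGAACATCAGCCACTGG	153	H_huso
153_HH	common	153_uni	TACTGTGCCTGTATGTCTCC	153	H_huso
247_AR	positive	247_ARp	TAAGGGTCCATGCATGCAG	247	A_ruthenus
247_AR	negative	247_ARn	TAAGGGTCCATGCATGCCT	247	A_ruthenus
247_AR	common	247_uni	TTTTAGCTGCACCGTGGC	247	A_ruthenus
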