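# published validation counts: specimens amplified / specimens tested, per primer pair and species
#pair	species	amplified	total
153_HHp	H_huso	47	47
153_HHp	A_ruthenus	0	120
153_HHp	A_baerii	0	40
153_HHp	H_dauricus	0	17
153_HHp	A_schrenckii	0	18
153_HHp	A_gueldenstaedtii	0	38
153_HHp	A_stellatus	0	40
153_HHp	A_persicus	0	21
153_HHp	A_mikadoi	0	8
153_HHp	A_transmontanus	0	32
153_HHp	bester	24	24
153_HHn	H_huso	0	47
153_HHn	A_ruthenus	120	120
153_HHn	A_baerii	40	40
153_HHn	H_dauricus	17	17
153_HHn	A_schrenckii	18	18
153_HHn	A_gueldenstaedtii	38	38
153_HHn	A_stellatus	40	40
153_HHn	A_persicus	21	21
153_HHn	A_mikadoi	8	8
153_HHn	A_transmontanus	32	32
153_HHn	bester	24	24
247_ARp	H_huso	0	47
247_ARp	A_ruthenus	120	120
247_ARp	A_baerii	0	40
247_ARp	H_dauricus	0	17
247_ARp	A_schrenckii	0	18
247_ARp	A_gueldenstaedtii	0	38
247_ARp	A_stellatus	0	40
247_ARp	A_persicus	0	21
247_ARp	A_mikadoi	0	8
247_ARp	A_transmontanus	0	32
247_ARp	bester	24	24
247_ARn	H_huso	47	47
247_ARn	A_ruthenus	0	120
247_ARn	A_baerii	40	40
247_ARn	H_dauricus	17	17
247_ARn	A_schrenckii	18	18
247_ARn	A_gueldenstaedtii	38	38
247_ARn	A_stellatus	23	40
247_ARn	A_persicus	21	21
247_ARn	A_mikadoi	8	8
247_ARn	A_transmontanus	32	32
247_ARn	bester	24	24
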